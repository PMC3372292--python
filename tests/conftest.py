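import numpy as np
import pytest

from pescore import GeneratorConfig, ProteinRecord, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def annotated_record():
    # 12 residues, hand-labeled: buried/exposed alternating, one disordered
    # stretch at the C terminus
    return ProteinRecord(
        id="p1",
        aa_seq="MKLIVDERAGSP",
        exposure="BEBEBEBEBEBE",
        disorder="OOOOOOOODDDD",
    )


@pytest.fixture
def cds_record():
    # AA seq "MRI" with Arg encoded by the rare codon AGA
    return ProteinRecord(id="p2", aa_seq="MRI", cds="ATGAGAATT")


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-construct cohort under default study conditions."""
    return generate_cohort(GeneratorConfig(n_constructs=400, seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no sequence effects and no E-S coupling."""
    config = GeneratorConfig(
        n_constructs=1500, seed=17,
        coefs_e={}, coefs_s={}, coupling=0.0,
        thresholds_e=(-0.8, -0.4, 0.0, 0.4, 0.8),
        thresholds_s=(-0.8, -0.4, 0.0, 0.4, 0.8),
        with_cds=False,
    )
    return generate_cohort(config)


def random_records(rng, n, length_range=(30, 120), with_annotations=True,
                   with_cds=False):
    """Plain random-composition records for property checks."""
    from pescore.scales import AA_TO_CODONS, STANDARD_AA
    from pescore.simulate import baseline_annotations

    aa = np.array(list(STANDARD_AA))
    records = []
    for i in range(n):
        length = int(rng.integers(*length_range))
        freqs = rng.dirichlet(np.ones(20) * 5.0)
        seq = "".join(rng.choice(aa, size=length, p=freqs))
        exposure = disorder = None
        if with_annotations:
            exposure, disorder = baseline_annotations(seq)
        cds = None
        if with_cds:
            cds = "".join(
                sorted(AA_TO_CODONS[res])[rng.integers(
                    len(AA_TO_CODONS[res]))]
                for res in seq)
        records.append(ProteinRecord(
            id=f"r{i:04d}", aa_seq=seq, cds=cds,
            exposure=exposure, disorder=disorder))
    return records
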