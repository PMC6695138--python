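import math

import pytest

from panelval import concordance, datasets, simulate


@pytest.fixture(scope="session")
def ref_calls():
    return datasets.load_reference_calls()


@pytest.fixture(scope="session")
def ref_labeled(ref_calls):
    return concordance.label_calls(ref_calls, datasets.reference_sanger_truth())


@pytest.fixture(scope="session")
def ref_clinical():
    return datasets.reference_clinical_truth()


@pytest.fixture(scope="session")
def ref_flags():
    return datasets.load_reference_flags()


def small_sim_config(seed=11, artifact_rate=0.5, **overrides):
    """A fast two-gene cohort with rare planted variants, one of them
    pathogenic, and artifact calls clustered in one region."""
    kw = dict(
        genes=(simulate.GeneSpec("G1", n_regions=3, region_length=120),
               simulate.GeneSpec("G2", n_regions=2, region_length=120)),
        n_samples_per_group={"AA": 6, "EA": 5},
        variant_model=(
            simulate.VariantSpec(gene="G1", offset=30,
                                 mafs={"AA": 0.02, "EA": 0.01},
                                 zygosity="all_het"),
            simulate.VariantSpec(gene="G2", region_index=1, offset=40,
                                 mafs={"AA": 0.01, "EA": None},
                                 zygosity="all_het", clinvar="Pathogenic"),
        ),
        artifact_model=simulate.ArtifactModel(
            rate=artifact_rate, pseudogene_region="G1_r1",
            pseudogene_rate=2.0),
        truth_model=simulate.TruthModel(screened_fraction=0.4),
        seed=seed,
    )
    kw.update(overrides)
    return simulate.SimulationConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate.simulate_panel(small_sim_config())


def approx_nan_safe(value, expected, **kw):
    if math.isnan(expected):
        return math.isnan(value)
    return value == pytest.approx(expected, **kw)
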