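import pytest

from bprisk.config import (
    AnalyteSpec,
    FoodCategory,
    GeneratorConfig,
    IntakeSpec,
    PopulationSpec,
    default_generator_config,
)


def single_pair_config(
    detection_rate: float = 1.0,
    gm: float = 34.0,
    gsd: float = 1.8,
    lod: float = 0.05,
    loq: float = 0.29,
    n_samples: int = 50,
    seed: int = 0,
    truncate_at_loq: bool = True,
    bw_mean: float = 60.0,
    bw_sd: float = 8.0,
    ir_gm: float = 100.0,
    ir_gsd: float = 1.5,
) -> GeneratorConfig:
    """One food category x one analyte x one age group, for focused tests."""
    return GeneratorConfig(
        seed=seed,
        food_categories=[FoodCategory(name="cereal", matrix_kind="solid", n_samples=n_samples)],
        analyte_specs={
            "cereal": {
                "BP": AnalyteSpec(
                    detection_rate=detection_rate, gm=gm, gsd=gsd, lod=lod, loq=loq
                )
            }
        },
        population_specs={
            "adult": PopulationSpec(
                bw_mean=bw_mean, bw_sd=bw_sd, ir={"cereal": IntakeSpec(gm=ir_gm, gsd=ir_gsd)}
            )
        },
        truncate_at_loq=truncate_at_loq,
    )


@pytest.fixture(scope="session")
def default_config():
    return default_generator_config(seed=0)


@pytest.fixture(scope="session")
def default_model():
    from bprisk import DietaryRiskModel

    return DietaryRiskModel.from_synthetic(seed=0)
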