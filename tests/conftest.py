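import numpy as np
import pytest

from chromoscore import SyntheticNucleusSpec, ThresholdConfig


@pytest.fixture
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


def random_nucleus_spec(rng: np.random.Generator, gapped: bool = False,
                        noise_sigma: float = 0.0) -> SyntheticNucleusSpec:
    """One random nucleus spec from the stated synthetic world.

    Inner radius 40-70 px and ring thickness 2.3-6.5 px span the Per-CS
    range the method reports (~2.3-6.3 px); particle density 1-7 per
    1,000 px spans Nuc-CS ~1-9%; a nucleolus, when present, occupies
    6-12% of the section.
    """
    inner = float(rng.uniform(40, 70))
    nucleolus = (
        float(rng.uniform(0.25, 0.35)) * inner if rng.uniform() < 0.5 else 0.0
    )
    gaps = ()
    if gapped:
        gaps = tuple(
            (float(rng.uniform(0, 360)), float(rng.uniform(5, 45)))
            for _ in range(int(rng.integers(1, 3)))
        )
    return SyntheticNucleusSpec(
        seed=int(rng.integers(2**31)),
        inner_radius=inner,
        ring_thickness=float(rng.uniform(2.3, 6.5)),
        particle_density=float(rng.uniform(1, 7)),
        nucleolus_radius=nucleolus,
        gap_arcs=gaps,
        noise_sigma=noise_sigma,
    )
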