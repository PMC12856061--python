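import numpy as np
import pytest

from osseoquant import synthetic


@pytest.fixture(scope="session")
def small_micrograph_spec():
    """Compact lattice (8x8 pore cells) to keep per-pixel oracles cheap."""
    return dict(width=360, height=360, margin=30, strut_pitch=33, strut_width=7)


@pytest.fixture(scope="session")
def micrograph_40(small_micrograph_spec):
    spec = synthetic.MicrographSpec(
        pore_fill={"interior": 0.4, "circumference": 0.4}, seed=7, **small_micrograph_spec
    )
    return synthetic.generate_micrograph(spec)


@pytest.fixture(scope="session")
def noiseless_curve():
    truth = synthetic.MaterialTruth(Er_true=13.0, H_true=0.46)
    return truth, synthetic.generate_indent_curve(truth)


def brute_force_region_percent(labels, region_mask):
    """Per-pixel recount of percent bone among non-scaffold region pixels.

    Intentionally a plain Python loop, independent of the vectorized path.
    """
    from osseoquant.histomorphometry import LABEL_BONE, LABEL_SCAFFOLD

    bone = 0
    denom = 0
    flat_labels = labels.ravel().tolist()
    flat_mask = region_mask.ravel().tolist()
    for lab, inside in zip(flat_labels, flat_mask):
        if not inside or lab == LABEL_SCAFFOLD:
            continue
        denom += 1
        if lab == LABEL_BONE:
            bone += 1
    if denom == 0:
        return float("nan"), 0
    return 100.0 * bone / denom, denom
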