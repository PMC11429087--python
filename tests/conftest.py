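import numpy as np
import pytest

import tectapipe as tp


@pytest.fixture(scope="session")
def short_lfp_cfg():
    """A 30-second recording config, long enough for stable backgrounds."""
    return tp.LFPSimConfig(duration_s=30.0, event_rate=0.0)


@pytest.fixture(scope="session")
def small_arbor_cfg():
    """Small radial trees for which pixel and geometric Sholl must agree."""
    return tp.ArborSimConfig(
        n_neurons=1,
        branch_prob=0.5,
        n_steps=4,
        segment_len_um=7.0,
        angle_jitter=0.15,
        field_um=(90.0, 90.0, 11.0),
        pixel_um=0.5,
        noise_sd=0.0,
    )


def rotate_tree_xy(tree: tp.ArborTree, angle: float) -> tp.ArborTree:
    """Rotate a tree about its soma in the lateral plane (test helper)."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def rt(p):
        return tree.soma + rot @ (p - tree.soma)

    return tp.ArborTree(
        soma=tree.soma.copy(),
        segments=[(rt(p), rt(q)) for p, q in tree.segments],
    )
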