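import numpy as np
import pytest

from retromimic import parse_sequence, retro_d_transform
from retromimic import synthetic as syn


@pytest.fixture(scope="session")
def hai():
    return parse_sequence("HAIYPRH")


@pytest.fixture(scope="session")
def retro_hai(hai):
    return retro_d_transform(hai)


@pytest.fixture(scope="session")
def thr():
    return parse_sequence("THRPPMWSPVWP")


@pytest.fixture(scope="session")
def small_pair(hai):
    """A mimic-mode parent/retro ensemble pair (10 frames, fixed seed)."""
    parent, retro, truth = syn.make_mimic_pair(
        hai, overlap_mode="mimic", noise_sigma=0.3, n_frames=10, seed=7
    )
    return parent, retro, truth


def quaternion_rmsd(x, y, weights=None):
    """Independent superposition oracle: Horn's quaternion eigenvalue
    method (restricted to proper rotations by construction)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
    wsum = w.sum()
    xc = x - (w[:, None] * x).sum(0) / wsum
    yc = y - (w[:, None] * y).sum(0) / wsum
    s = (w[:, None] * yc).T @ xc  # S[a, b] = sum w * y_a * x_b
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (w[:, None] * (xc**2 + yc**2)).sum()
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / wsum))
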