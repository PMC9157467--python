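"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately written from first principles (normal
equations, exhaustive pair enumeration, batched Kabsch from raw SVD) and
never calls the code paths it validates.
"""

from __future__ import annotations

import numpy as np


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and slope standard error via the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    if n > 2:
        stderr = np.sqrt(np.sum(resid**2) / (n - 2) / sxx)
    else:
        stderr = 0.0
    return float(slope), float(intercept), float(stderr)


def brute_force_hbonds(model, max_ho, max_no, min_angle):
    """Exhaustive all-pairs N-H...O=C search; returns every qualifying
    (donor_residue, acceptor_residue) pair without donor deduplication."""
    ns, hs, os_ = {}, {}, []
    for a in model.atoms:
        if a.name == "N":
            ns[(a.chain_id, a.residue_number)] = a.pos
        elif a.name == "H":
            hs[(a.chain_id, a.residue_number)] = a.pos
        elif a.name == "O":
            os_.append((a.chain_id, a.residue_number, a.pos))
    pairs = []
    for (chain, res), h in hs.items():
        if (chain, res) not in ns:
            continue
        n = ns[(chain, res)]
        for ochain, ores, o in os_:
            if ochain == chain and abs(ores - res) < 2:
                continue
            d_ho = np.linalg.norm(o - h)
            d_no = np.linalg.norm(o - n)
            v1, v2 = n - h, o - h
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if d_ho <= max_ho and d_no <= max_no and ang >= min_angle:
                pairs.append(((chain, res), (ochain, ores), float(d_ho)))
    return pairs


def kabsch_batched(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper-rotation Kabsch for stacked point sets (..., N, 3) -> fitted mobile."""
    mob_c = mobile - mobile.mean(axis=-2, keepdims=True)
    ref_c = reference - reference.mean(axis=-2, keepdims=True)
    h = np.einsum("...ni,...nj->...ij", mob_c, ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("...ij,...jk->...ik", u, vt)))
    u[..., :, -1] *= d[..., None]
    rot = np.einsum("...ij,...jk->...ik", u, vt)
    return np.einsum("...ni,...ij->...nj", mob_c, rot) + reference.mean(
        axis=-2, keepdims=True
    )


def fit_to_mean_rmsd_mc(
    base: np.ndarray, n_models: int, sigma: float, n_replicates: int, seed: int,
    n_iter: int = 10,
) -> float:
    """Monte-Carlo expectation of the iterative fit-to-mean mean r.m.s.d. for
    Gaussian coordinate noise of ``sigma`` around ``base`` (N, 3)."""
    rng = np.random.default_rng(seed)
    coords = base[None, None] + rng.normal(
        0.0, sigma, size=(n_replicates, n_models, *base.shape)
    )
    mean = coords[:, 0].copy()
    fitted = coords
    for _ in range(n_iter):
        fitted = kabsch_batched(coords, mean[:, None])
        mean = fitted.mean(axis=1)
    sq = np.mean(np.sum((fitted - mean[:, None]) ** 2, axis=-1), axis=-1)
    return float(np.mean(np.sqrt(sq)))
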