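"""Structure-preserving H&E color normalization by sparse stain separation.

The RGB image is converted to optical density X = -log(I / I0) under the
Beer-Lambert law, then factorized as X ~= W L with W a 3 x r color-appearance
matrix (unit-norm, nonnegative columns) and L an r x n_pixels nonnegative
stain-density map, by minimizing

    0.5 ||X - W L||_F^2  +  lambda * sum_j ||L(j,:)||_1 ,
    subject to W >= 0, ||W(:,j)||_2 <= 1, L >= 0.

Normalization to a target image rescales each source density row by the
ratio of target to source pseudo-maxima (the 99th-percentile row value) and
recombines with the *target's* color matrix, so the source's spatial stain
structure is preserved while its color appearance follows the target:

    L_norm(j,:) = L_s(j,:) * pseudomax(L_t(j,:)) / pseudomax(L_s(j,:))
    I_norm      = I0 * exp(-W_t @ L_norm)

The factorization is solved by alternating convex updates that are each
exact or guaranteed-descent steps, so the objective is monotone
non-increasing across iterations: coordinate-descent nonnegative lasso for
L, and projected gradient on the capped nonnegative ball for W.  After the
sparse fit converges, the density map actually applied to pixels is
re-solved with lambda = 0 given the fixed W (standard lasso debiasing), so
self-normalization reproduces the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthesis import EOSIN_OD, HEMATOXYLIN_OD

log = logging.getLogger(__name__)


@dataclass
class NormalizationConfig:
    I0: float = 255.0
    lam: float = 0.1
    r: int = 2
    pseudo_max_percentile: float = 0.99
    od_background_threshold: float = 0.15
    max_fit_pixels: int = 20000
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.r < 1:
            raise ValueError("number of stains r must be >= 1")
        if not 0.0 < self.pseudo_max_percentile <= 1.0:
            raise ValueError("pseudo_max_percentile must be in (0, 1]")


@dataclass
class OpticalDensityImage:
    """Pixel-unrolled OD matrix (3 x n_pixels) plus shape bookkeeping."""

    values: np.ndarray
    source_shape: tuple[int, int]
    i0: float = 255.0


@dataclass
class StainModel:
    """Fitted color-appearance matrix and per-pixel stain densities."""

    w: np.ndarray          # (3, r), unit-norm nonnegative columns
    l: np.ndarray          # (r, n_pixels), nonnegative (debiased)
    lam: float
    r: int
    objective_history: list = field(default_factory=list)

    @property
    def objective(self) -> float:
        return self.objective_history[-1]


def rgb_to_od(image: np.ndarray, config: NormalizationConfig | None = None
              ) -> OpticalDensityImage:
    """Beer-Lambert conversion: X = -log(max(I, 1) / I0)."""
    config = config or NormalizationConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {image.shape}")
    h, w, _ = image.shape
    flat = image.reshape(-1, 3).T.astype(float)
    x = -np.log(np.maximum(flat, 1.0) / config.I0)
    return OpticalDensityImage(values=x, source_shape=(h, w), i0=config.I0)


def od_to_rgb(od: OpticalDensityImage) -> np.ndarray:
    """Inverse Beer-Lambert back to an 8-bit RGB image."""
    h, w = od.source_shape
    img = od.i0 * np.exp(-od.values)
    return np.clip(np.rint(img.T.reshape(h, w, 3)), 0, 255).astype(np.uint8)


def pseudo_max(row: np.ndarray, percentile: float = 0.99) -> float:
    """Empirical percentile-quantile (linear interpolation) of a density row."""
    row = np.asarray(row, float).ravel()
    if row.size == 0:
        raise ValueError("pseudo_max of an empty row is undefined")
    return float(np.quantile(row, percentile))


def _objective(x, w, l, lam):
    resid = x - w @ l
    return 0.5 * float(np.sum(resid * resid)) + lam * float(np.abs(l).sum())


def _update_l(x, w, l, lam, sweeps=8):
    """Coordinate-descent nonnegative lasso on each density row (exact steps)."""
    r = w.shape[1]
    wtx = w.T @ x                        # (r, n)
    gram = w.T @ w                       # (r, r)
    for _ in range(sweeps):
        for j in range(r):
            # numerator: w_j' (x - sum_{k!=j} w_k l_k) - lam
            num = wtx[j] - gram[j] @ l + gram[j, j] * l[j] - lam
            l[j] = np.maximum(num / max(gram[j, j], 1e-12), 0.0)
    return l


def _project_w(w):
    """Projection onto {w >= 0, ||w||_2 <= 1} column-wise."""
    w = np.maximum(w, 0.0)
    norms = np.linalg.norm(w, axis=0)
    over = norms > 1.0
    w[:, over] /= norms[over]
    return w


def _update_w(x, w, l, steps=8):
    """Projected gradient descent on W (Lipschitz step size => descent)."""
    llt = l @ l.T
    lip = max(float(np.linalg.norm(llt, 2)), 1e-12)
    xlt = x @ l.T
    for _ in range(steps):
        grad = w @ llt - xlt
        w = _project_w(w - grad / lip)
    return w


def _init_w(r: int, rng: np.random.Generator) -> np.ndarray:
    w = np.stack([HEMATOXYLIN_OD, EOSIN_OD], axis=1).astype(float)
    if r > 2:
        extra = rng.uniform(0.05, 1.0, size=(3, r - 2))
        w = np.concatenate([w, extra], axis=1)
    w = w[:, :r]
    return _project_w(w / np.linalg.norm(w, axis=0))


def _order_stains(w, l):
    """Fix the NMF permutation: stain 1 is the hematoxylin-like column.

    The first two columns are assigned to (hematoxylin, eosin) by whichever
    pairing has the greater total cosine similarity to the Ruifrok H&E
    reference vectors; this stays stable even when a stain's blue or red
    absorbance is nearly zero.
    """
    if w.shape[1] < 2:
        return w, l
    href = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
    eref = EOSIN_OD / np.linalg.norm(EOSIN_OD)
    wn = w / np.maximum(np.linalg.norm(w, axis=0), 1e-12)
    best, best_score = None, -np.inf
    for i in range(w.shape[1]):
        for j in range(w.shape[1]):
            if i == j:
                continue
            score = wn[:, i] @ href + wn[:, j] @ eref
            if score > best_score:
                best, best_score = (i, j), score
    rest = [k for k in range(w.shape[1]) if k not in best]
    order = list(best) + rest
    return w[:, order], l[order]


def fit_stain_model(od: OpticalDensityImage,
                    config: NormalizationConfig | None = None) -> StainModel:
    """Sparse nonnegative stain separation of an OD image.

    W is fitted on a seeded subsample of tissue pixels (OD norm above the
    background threshold); the returned density map L is then re-solved for
    every pixel with the sparsity penalty removed (debiasing), given W.
    """
    config = config or NormalizationConfig()
    x_all = od.values
    tissue = np.linalg.norm(x_all, axis=0) > config.od_background_threshold
    n_tissue = int(tissue.sum())
    if n_tissue < config.r:
        raise ValueError("no tissue pixels above OD threshold")

    x_fit = x_all[:, tissue]
    if n_tissue > config.max_fit_pixels:
        rng = np.random.default_rng(config.seed)
        keep = rng.choice(n_tissue, size=config.max_fit_pixels, replace=False)
        keep.sort()
        x_fit = x_fit[:, keep]

    rng = np.random.default_rng(config.seed + 1)
    w = _init_w(config.r, rng)
    l = np.maximum(np.linalg.lstsq(w, x_fit, rcond=None)[0], 0.0)
    history = [_objective(x_fit, w, l, config.lam)]
    for _ in range(config.max_iter):
        l = _update_l(x_fit, w, l, config.lam)
        w = _update_w(x_fit, w, l)
        obj = _objective(x_fit, w, l, config.lam)
        history.append(obj)
        if abs(history[-2] - obj) <= config.tol * max(abs(history[-2]), 1e-12):
            break

    w, _ = _order_stains(w, l)
    # Debiased densities for every pixel (lambda = 0, fixed W), warm-started
    # from the clipped least-squares projection so coordinate descent
    # converges even for coherent dictionaries.
    l_full = np.maximum(np.linalg.lstsq(w, x_all, rcond=None)[0], 0.0)
    l_full = _update_l(x_all, w, l_full, lam=0.0, sweeps=30)
    return StainModel(w=w, l=l_full, lam=config.lam, r=config.r,
                      objective_history=history)


def normalize_to_target(source: np.ndarray, target: np.ndarray,
                        config: NormalizationConfig | None = None,
                        *, return_models: bool = False):
    """Normalize the source image's stain appearance to the target's.

    Fits stain models to both images, scales each source density row by the
    ratio of target to source pseudo-maxima, recombines with the target's
    color matrix and exponentiates back to 8-bit RGB.
    """
    config = config or NormalizationConfig()
    if np.asarray(source).shape[-1] != np.asarray(target).shape[-1]:
        raise ValueError("source and target channel counts differ")
    od_s = rgb_to_od(source, config)
    od_t = rgb_to_od(target, config)
    model_s = fit_stain_model(od_s, config)
    model_t = fit_stain_model(od_t, config)

    p = config.pseudo_max_percentile
    ls_rm = np.array([pseudo_max(model_s.l[j], p) for j in range(config.r)])
    lt_rm = np.array([pseudo_max(model_t.l[j], p) for j in range(config.r)])
    ratio = lt_rm / np.maximum(ls_rm, 1e-12)
    l_norm = model_s.l * ratio[:, None]

    x_norm = model_t.w @ l_norm
    h, w = od_s.source_shape
    out = np.clip(np.rint(config.I0 * np.exp(-x_norm).T.reshape(h, w, 3)),
                  0, 255).astype(np.uint8)
    if return_models:
        return out, {"source": model_s, "target": model_t,
                     "l_norm": l_norm, "ratio": ratio,
                     "pseudo_max_source": ls_rm, "pseudo_max_target": lt_rm}
    return out


def hematoxylin_density_map(image: np.ndarray,
                            config: NormalizationConfig | None = None
                            ) -> np.ndarray:
    """Per-pixel hematoxylin stain density of an RGB image (2-D map).

    Returns an all-zero map for images with no tissue pixels.
    """
    config = config or NormalizationConfig()
    od = rgb_to_od(image, config)
    tissue = np.linalg.norm(od.values, axis=0) > config.od_background_threshold
    if int(tissue.sum()) < config.r:
        return np.zeros(od.source_shape)
    model = fit_stain_model(od, config)
    return model.l[0].reshape(od.source_shape)
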