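"""Cascaded glioma grading with molecular and cellularity fusion.

Three-way grading (LGG II, LGG III, HGG IV) is posed as two sequential
binary problems: a plain convolutional network first separates HGG from
LGG, and a deeper residual network then separates LGG II from III — the
extra depth targets the subtler difference between adjacent lower grades.
Both networks fuse the image representation with a binary 4-marker
molecular vector (IDH, ATRX, 1p/19q, MGMT) and the cellularity scalar by
concatenation before the first dense layer; each block can be ablated via
presence flags.

Also here: patch tiling and augmentation, case-stratified cross-validation,
and the reverse task of predicting molecular status from image-derived
features, cellularity, histology and grade with a small feed-forward
classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.transform import rescale, resize
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import nn
from .records import CaseRecord

log = logging.getLogger(__name__)

GRADE_ORDER = ("II", "III", "IV")


# ---------------------------------------------------------------------------
# patches and augmentation
# ---------------------------------------------------------------------------

def make_patches(roi: np.ndarray, patch_size: int = 512) -> list[np.ndarray]:
    """Tile an ROI into covering ``patch_size`` squares.

    Per axis, ``ceil(dim / patch_size)`` evenly spaced windows cover the
    whole ROI; windows overlap when the size does not divide evenly (a
    1000-px ROI with 512-px patches gives starts 0 and 488, hence a 2x2
    grid of four patches).
    """
    roi = np.asarray(roi)
    h, w = roi.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"ROI {h}x{w} smaller than patch size {patch_size}"
        )

    def starts(dim):
        n = int(np.ceil(dim / patch_size))
        if n == 1:
            return [0]
        return [int(round(v)) for v in np.linspace(0, dim - patch_size, n)]

    return [
        roi[r : r + patch_size, c : c + patch_size]
        for r in starts(h)
        for c in starts(w)
    ]


def augment_params(seed: int) -> tuple[int, int, float]:
    """The (rotation quarter-turns, flip code, scale) an augment seed draws.

    Flip code: 0 none, 1 horizontal, 2 vertical.
    """
    rng = np.random.default_rng(seed)
    return (int(rng.integers(0, 4)), int(rng.integers(0, 3)),
            float(rng.uniform(0.95, 1.1)))


def augment(patch: np.ndarray, seed: int) -> np.ndarray:
    """Random right-angle rotation, flip and 0.95-1.1x scale (seeded).

    The scaled image is center-cropped or edge-padded back to the input
    size, so output dimensions always equal input dimensions.  Scale
    factors within 1% of 1 are treated as identity.
    """
    patch = np.asarray(patch)
    h, w = patch.shape[:2]
    k, flip, scale = augment_params(seed)
    if h != w and k % 2 == 1:
        raise ValueError("90/270 degree rotation requires a square patch")
    out = np.rot90(patch, k)
    if flip == 1:
        out = out[:, ::-1]
    elif flip == 2:
        out = out[::-1, :]
    if abs(scale - 1.0) > 0.01:
        scaled = rescale(out.astype(float), scale, channel_axis=-1 if out.ndim == 3 else None,
                         anti_aliasing=scale < 1.0, preserve_range=True)
        out = _fit_to(scaled, h, w)
        out = np.clip(np.rint(out), 0, 255).astype(patch.dtype)
    return np.ascontiguousarray(out)


def _fit_to(img: np.ndarray, h: int, w: int) -> np.ndarray:
    ih, iw = img.shape[:2]
    if ih >= h:
        r0 = (ih - h) // 2
        img = img[r0 : r0 + h]
    if iw >= w:
        c0 = (iw - w) // 2
        img = img[:, c0 : c0 + w]
    ph, pw = h - img.shape[0], w - img.shape[1]
    if ph > 0 or pw > 0:
        pad = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
        if img.ndim == 3:
            pad.append((0, 0))
        img = np.pad(img, pad, mode="edge")
    return img


def split_folds(records: list[CaseRecord], k: int = 5, seed: int = 0):
    """Case-level stratified k-fold assignments (all patches share a fold).

    Returns a list of ``(train_idx, test_idx)`` index arrays; stratification
    is by grade, giving the 80/20 train/test ratio per class at k = 5.
    """
    grades = [r.grade for r in records]
    for g in set(grades):
        if grades.count(g) < k:
            raise ValueError(f"class {g} has fewer than {k} cases")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(records)), grades))


# ---------------------------------------------------------------------------
# fusion networks
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    input_size: int = 48          # patches are resized to this before the net
    patch_size: int | None = None  # None: one patch = the whole ROI
    epochs: int = 25
    batch_size: int = 12
    lr: float = 2e-3
    use_intensity: bool = True
    use_molecular: bool = True
    use_cellularity: bool = True
    augment_training: bool = True
    stage1_width: int = 8
    stage2_width: int = 8
    hidden: int = 32
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (self.use_intensity or self.use_molecular or self.use_cellularity):
            raise ValueError("no active feature block")

    @property
    def tab_dim(self) -> int:
        return (8 if self.use_molecular else 0) + (1 if self.use_cellularity else 0)


# Fixed standardization constants for the cellularity input: typical H&E
# cellularity values span ~0.1-0.45, so this centers the feature and gives
# it unit-order scale comparable to the binary molecular indicators.
CELL_MEAN = 0.25
CELL_SCALE = 0.1


def tabular_features(record: CaseRecord, config: ClassifierConfig) -> np.ndarray:
    parts = []
    if config.use_molecular:
        parts.append(record.molecular_vector)
    if config.use_cellularity:
        if record.cellularity is None:
            raise ValueError(f"case {record.case_id} has no cellularity")
        parts.append(np.array([(record.cellularity - CELL_MEAN) / CELL_SCALE]))
    return np.concatenate(parts) if parts else np.zeros(0)


class GlobalAvgPool:
    def params(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class ResidualBlock:
    """Two 3x3 convolutions with an identity skip: y = relu(f(x) + x)."""

    def __init__(self, channels, rng):
        self.conv1 = nn.Conv2d(channels, channels, rng=rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(channels, channels, rng=rng)
        self.relu_out = nn.ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x):
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(y + x)

    def backward(self, dout):
        g = self.relu_out.backward(dout)
        gx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return gx + g


class FusionClassifier:
    """Conv trunk + tabular concatenation + dense head, binary softmax."""

    def __init__(self, trunk: list, tab_dim: int, hidden: int,
                 input_size: int, rng: np.random.Generator,
                 use_intensity: bool = True):
        self.trunk = trunk if use_intensity else []
        self.use_intensity = use_intensity
        self.tab_dim = tab_dim
        if use_intensity:
            probe = np.zeros((1, 3, input_size, input_size))
            for layer in self.trunk:
                probe = layer.forward(probe)
            feat_dim = probe.shape[1]
        else:
            feat_dim = 0
        self.fc1 = nn.Dense(feat_dim + tab_dim, hidden, rng=rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Dense(hidden, 2, rng=rng)
        self._feat_dim = feat_dim

    def params(self):
        ps = []
        for layer in self.trunk:
            ps.extend(layer.params())
        return ps + self.fc1.params() + self.fc2.params()

    def forward(self, x_img, x_tab):
        if self.use_intensity:
            h = x_img
            for layer in self.trunk:
                h = layer.forward(h)
        else:
            h = np.zeros((x_tab.shape[0], 0))
        z = np.concatenate([h, x_tab], axis=1)
        return self.fc2.forward(self.relu.forward(self.fc1.forward(z)))

    def backward(self, dlogits):
        g = self.fc1.backward(self.relu.backward(self.fc2.backward(dlogits)))
        if self.use_intensity:
            g_img = g[:, : self._feat_dim]
            for layer in reversed(self.trunk):
                g_img = layer.backward(g_img)


def _stage1_trunk(width, rng):
    w = width
    return [
        nn.Conv2d(3, w, rng=rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2d(w, 2 * w, rng=rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2d(2 * w, 2 * w, rng=rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2d(2 * w, 4 * w, rng=rng), nn.ReLU(), nn.MaxPool2(),
        GlobalAvgPool(),
    ]


def _stage2_trunk(width, rng):
    w = width
    return [
        nn.Conv2d(3, w, rng=rng), nn.ReLU(), nn.MaxPool2(),
        ResidualBlock(w, rng), ResidualBlock(w, rng), nn.MaxPool2(),
        nn.Conv2d(w, 2 * w, rng=rng), nn.ReLU(),
        ResidualBlock(2 * w, rng), ResidualBlock(2 * w, rng), nn.MaxPool2(),
        ResidualBlock(2 * w, rng), ResidualBlock(2 * w, rng),
        GlobalAvgPool(),
    ]


STAGE1_CONV_LAYERS = 4
STAGE2_RESIDUAL_BLOCKS = 6


@dataclass
class StageModel:
    net: FusionClassifier
    config: ClassifierConfig
    positive_label: str          # "IV" for stage 1, "III" for stage 2
    loss_history: list = field(default_factory=list)

    def patch_probabilities(self, record: CaseRecord) -> np.ndarray:
        patches = _record_patches(record, self.config)
        x = np.stack([_prep_patch(p, self.config.input_size) for p in patches])
        tab = np.tile(tabular_features(record, self.config), (len(patches), 1))
        logits = self.net.forward(x, tab)
        return nn.softmax(logits, axis=1)[:, 1]

    def case_probability(self, record: CaseRecord) -> float:
        """Mean of patch probabilities (case-level aggregation)."""
        return float(self.patch_probabilities(record).mean())


def _record_patches(record: CaseRecord, config: ClassifierConfig):
    img = record.image
    if img is None:
        raise ValueError(f"case {record.case_id} has no image")
    if config.patch_size is None:
        return [img]
    return make_patches(img, config.patch_size)


# Standardization constants for brightfield H&E patches (approximate
# transmitted-light mean/spread after division by 255).
IMG_MEAN = 0.7
IMG_STD = 0.25


def _prep_patch(patch: np.ndarray, size: int) -> np.ndarray:
    if patch.shape[0] != size or patch.shape[1] != size:
        patch = resize(patch.astype(float), (size, size), anti_aliasing=True,
                       preserve_range=True)
    x = (np.asarray(patch, float) / 255.0 - IMG_MEAN) / IMG_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def _augment_array(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Training-time augmentation on a prepped (C, H, W) array: right-angle
    rotation, flip, and 0.95-1.1x scale jitter (crop/pad back)."""
    k = int(rng.integers(0, 4))
    x = np.rot90(x, k, axes=(1, 2))
    flip = rng.integers(0, 3)
    if flip == 1:
        x = x[:, :, ::-1]
    elif flip == 2:
        x = x[:, ::-1, :]
    scale = float(rng.uniform(0.95, 1.1))
    if abs(scale - 1.0) > 0.01:
        from scipy.ndimage import zoom

        _, h, w = x.shape
        z = zoom(x, (1, scale, scale), order=1)
        x = _fit_to(z.transpose(1, 2, 0), h, w).transpose(2, 0, 1)
    return np.ascontiguousarray(x)


def _train_fusion(records, labels, trunk_factory, width, config, seed):
    rng = np.random.default_rng(seed)
    trunk = trunk_factory(width, rng)
    net = FusionClassifier(trunk, config.tab_dim, config.hidden,
                           config.input_size, rng,
                           use_intensity=config.use_intensity)
    opt = nn.Adam(net.params(), lr=config.lr)

    base_patches, tabs, ys = [], [], []
    for rec, y in zip(records, labels):
        for p in _record_patches(rec, config):
            base_patches.append(_prep_patch(p, config.input_size))
            tabs.append(tabular_features(rec, config))
            ys.append(y)
    x_all = np.stack(base_patches)
    tabs = np.asarray(tabs)
    ys = np.asarray(ys, int)
    n = len(base_patches)

    loss_history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if config.augment_training and config.use_intensity:
                x = np.stack([_augment_array(x_all[i], rng) for i in idx])
            else:
                x = x_all[idx]
            logits = net.forward(x, tabs[idx])
            loss, dlogits = nn.softmax_cross_entropy(logits, ys[idx])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        loss_history.append(float(np.mean(losses)))
    return net, loss_history


def train_stage1(train_records: list[CaseRecord],
                 config: ClassifierConfig | None = None) -> StageModel:
    """HGG-vs-LGG classifier: plain CNN (no residual connections) + fusion."""
    config = config or ClassifierConfig()
    labels = [int(r.grade == "IV") for r in train_records]
    if len(set(labels)) < 2:
        raise ValueError("stage 1 training needs both HGG and LGG cases")
    net, hist = _train_fusion(train_records, labels, _stage1_trunk,
                              config.stage1_width, config, config.seed)
    return StageModel(net=net, config=config, positive_label="IV",
                      loss_history=hist)


def train_stage2(train_records: list[CaseRecord],
                 config: ClassifierConfig | None = None) -> StageModel:
    """LGG II-vs-III classifier: residual network + fusion (deeper than stage 1)."""
    config = config or ClassifierConfig()
    if any(r.grade == "IV" for r in train_records):
        raise ValueError("stage 2 trains on LGG (grade II/III) records only")
    labels = [int(r.grade == "III") for r in train_records]
    if len(set(labels)) < 2:
        raise ValueError("stage 2 training needs both grade II and III cases")
    net, hist = _train_fusion(train_records, labels, _stage2_trunk,
                              config.stage2_width, config, config.seed + 1)
    return StageModel(net=net, config=config, positive_label="III",
                      loss_history=hist)


def predict_cascade(record: CaseRecord, stage1: StageModel,
                    stage2: StageModel) -> str:
    """Stepwise grade call: HGG first, then II vs III for LGG cases.

    Case-level mean patch probability, threshold 0.5 with ties to the
    higher grade; stage 2 is never invoked for an HGG verdict.
    """
    for m in (stage1, stage2):
        if m.config.use_cellularity and record.cellularity is None:
            raise ValueError(
                f"case {record.case_id}: model expects cellularity but the "
                "record has none"
            )
    if stage1.case_probability(record) >= 0.5:
        return "IV"
    return "III" if stage2.case_probability(record) >= 0.5 else "II"


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    task: str
    per_fold_accuracy: list[float]
    mean_accuracy: float
    std_accuracy: float
    confusion_matrix: np.ndarray
    labels: tuple

    def summary(self) -> str:
        """Accuracy in 'mean% +/- std%' form."""
        return f"{100 * self.mean_accuracy:.2f}% ± {100 * self.std_accuracy:.2f}%"

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "per_fold_accuracy": list(map(float, self.per_fold_accuracy)),
            "mean_accuracy": float(self.mean_accuracy),
            "std_accuracy": float(self.std_accuracy),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "labels": list(self.labels),
        }


def _make_report(task, fold_accs, confusion, labels) -> CVReport:
    accs = np.asarray(fold_accs, float)
    std = float(accs.std(ddof=1)) if accs.size > 1 else 0.0
    return CVReport(task=task, per_fold_accuracy=list(map(float, accs)),
                    mean_accuracy=float(accs.mean()), std_accuracy=std,
                    confusion_matrix=confusion, labels=labels)


def evaluate_cv(records: list[CaseRecord], task: str,
                config: ClassifierConfig | None = None) -> CVReport:
    """k-fold case-level cross-validation of a grading task.

    ``task``: ``'HGGvsLGG'`` (stage 1), ``'LGGIIvsIII'`` (stage 2 on LGG
    cases), or ``'cascade'`` (full three-grade pipeline).
    """
    config = config or ClassifierConfig()
    if task == "LGGIIvsIII":
        records = [r for r in records if r.grade in ("II", "III")]
    folds = split_folds(records, k=config.folds, seed=config.seed)
    if task == "HGGvsLGG":
        labels = ("LGG", "HGG")
    elif task == "LGGIIvsIII":
        labels = ("II", "III")
    elif task == "cascade":
        labels = GRADE_ORDER
    else:
        raise ValueError(f"unknown task {task!r}")

    confusion = np.zeros((len(labels), len(labels)), int)
    fold_accs = []
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        fold_cfg = ClassifierConfig(**{**config.__dict__,
                                       "seed": config.seed + 101 * fold_i})
        if task == "HGGvsLGG":
            model = train_stage1(train, fold_cfg)
            truth = [int(r.grade == "IV") for r in test]
            pred = [int(model.case_probability(r) >= 0.5) for r in test]
        elif task == "LGGIIvsIII":
            model = train_stage2(train, fold_cfg)
            truth = [int(r.grade == "III") for r in test]
            pred = [int(model.case_probability(r) >= 0.5) for r in test]
        else:
            stage1 = train_stage1(train, fold_cfg)
            stage2 = train_stage2([r for r in train if r.grade != "IV"], fold_cfg)
            truth = [GRADE_ORDER.index(r.grade) for r in test]
            pred = [GRADE_ORDER.index(predict_cascade(r, stage1, stage2))
                    for r in test]
        truth = np.asarray(truth)
        pred = np.asarray(pred)
        fold_accs.append(float((truth == pred).mean()))
        for t, p in zip(truth, pred):
            confusion[t, p] += 1
    return _make_report(task, fold_accs, confusion, labels)


def cross_validate_cascade(records: list[CaseRecord],
                           config: ClassifierConfig | None = None):
    """Full-cascade CV returning the report and per-case predictions.

    Predictions carry the case-level stage probabilities; ``stage2_prob``
    is empty for cases the cascade short-circuits to HGG.
    """
    import pandas as pd

    config = config or ClassifierConfig()
    folds = split_folds(records, k=config.folds, seed=config.seed)
    confusion = np.zeros((3, 3), int)
    fold_accs, rows = [], []
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        train = [records[i] for i in train_idx]
        fold_cfg = ClassifierConfig(**{**config.__dict__,
                                       "seed": config.seed + 101 * fold_i})
        stage1 = train_stage1(train, fold_cfg)
        stage2 = train_stage2([r for r in train if r.grade != "IV"], fold_cfg)
        correct = 0
        for i in test_idx:
            rec = records[i]
            p1 = stage1.case_probability(rec)
            if p1 >= 0.5:
                pred, p2 = "IV", None
            else:
                p2 = stage2.case_probability(rec)
                pred = "III" if p2 >= 0.5 else "II"
            confusion[GRADE_ORDER.index(rec.grade), GRADE_ORDER.index(pred)] += 1
            correct += int(pred == rec.grade)
            rows.append({"case_id": rec.case_id, "fold": fold_i,
                         "true_grade": rec.grade, "predicted_grade": pred,
                         "stage1_prob": round(p1, 6),
                         "stage2_prob": "" if p2 is None else round(p2, 6)})
        fold_accs.append(correct / len(test_idx))
    report = _make_report("cascade", fold_accs, confusion, GRADE_ORDER)
    preds = pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)
    return report, preds


# ---------------------------------------------------------------------------
# molecular-status classification
# ---------------------------------------------------------------------------

_MOLECULAR_POSITIVE = {"idh": "MT", "codel_1p19q": "CD", "atrx": "MT"}
_HISTOLOGY_ORDER = ("AA", "OA", "OD", "GBM")


def image_summary_features(record: CaseRecord) -> np.ndarray:
    """Image-derived summary statistics: per-channel mean/std of the ROI,
    nuclei count and mean nucleus area (from the nuclei mask)."""
    img = np.asarray(record.image, float)
    chan_mean = img.mean(axis=(0, 1))
    chan_std = img.std(axis=(0, 1))
    labeled = cc_label(np.asarray(record.mask) > 0)
    count = int(labeled.max())
    fg = int((labeled > 0).sum())
    mean_area = fg / count if count else 0.0
    return np.concatenate([chan_mean, chan_std, [count, mean_area]])


def classify_molecular(records: list[CaseRecord], target: str,
                       features=("image", "cellularity", "histology", "grade"),
                       *, repeats: int = 10, seed: int = 0,
                       hidden: int = 16) -> CVReport:
    """Predict a molecular status with repeated stratified 5-fold CV.

    ``target`` is one of ``idh``, ``codel_1p19q``, ``atrx``; ``features``
    any nonempty subset of ``{'image', 'cellularity', 'histology',
    'grade'}``.  The classifier is a small feed-forward network on the
    standardized tabular feature vector.
    """
    if target not in _MOLECULAR_POSITIVE:
        raise ValueError(f"target must be one of {sorted(_MOLECULAR_POSITIVE)}")
    features = tuple(features)
    allowed = {"image", "cellularity", "histology", "grade"}
    if not features:
        raise ValueError("at least one feature group is required")
    unknown = set(features) - allowed
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")

    rows, y = [], []
    for rec in records:
        parts = []
        if "image" in features:
            parts.append(image_summary_features(rec))
        if "cellularity" in features:
            if rec.cellularity is None:
                raise ValueError(f"case {rec.case_id} has no cellularity")
            parts.append([rec.cellularity])
        if "histology" in features:
            parts.append([float(rec.histology == h) for h in _HISTOLOGY_ORDER])
        if "grade" in features:
            parts.append([float(rec.grade == g) for g in GRADE_ORDER])
        rows.append(np.concatenate([np.atleast_1d(p) for p in parts]))
        y.append(int(getattr(rec, target) == _MOLECULAR_POSITIVE[target]))
    x = np.asarray(rows)
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError(f"target {target} has a single class in this cohort")

    cv = RepeatedStratifiedKFold(n_splits=5, n_repeats=repeats,
                                 random_state=seed)
    accs = []
    confusion = np.zeros((2, 2), int)
    for train_idx, test_idx in cv.split(x, y):
        clf = make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(hidden,), solver="lbfgs",
                          max_iter=2000, random_state=seed),
        )
        clf.fit(x[train_idx], y[train_idx])
        pred = clf.predict(x[test_idx])
        accs.append(float((pred == y[test_idx]).mean()))
        for t, p in zip(y[test_idx], pred):
            confusion[t, p] += 1
    labels = ("negative", _MOLECULAR_POSITIVE[target])
    return _make_report(f"molecular:{target}", accs, confusion, labels)
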