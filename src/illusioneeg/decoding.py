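"""Cross-language EEG decoding: CSP -> mutual information -> QDA.

The decoder is trained on audiobook-listening segments (two classes:
English and Italian speech) and exploits differences in spatial covariance
structure rather than stimulus-locked waveforms:

1. Per-segment channel covariances are trace-normalized and class-averaged;
   CSP filters solve the generalized eigenproblem of (C_a, C_a + C_b), so
   each component's class-A eigenvalue lambda pairs with 1 - lambda for
   class B.  Components are ordered by discriminability max(lambda, 1-lambda).
2. Per-segment features are the log variance of each spatially filtered
   segment; a plug-in binned mutual-information estimate between each
   feature and the class label ranks the features.
3. A quadratic discriminant classifier with optional shrinkage models the
   class-specific feature covariances.

Evaluation is leave-one-subject-out with an inner repeated stratified
10-fold selecting (n_components, k_features, shrinkage) on the pooled
training subjects.  Group-averaged main-task condition trials can be
projected through a trained pipeline to obtain per-condition class
percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .containers import EpochSet, concatenate_epochs

logger = logging.getLogger(__name__)

__all__ = [
    "CSPModel",
    "FeatureSelection",
    "QDAModel",
    "DecoderSettings",
    "LanguageDecoder",
    "epoch_covariances",
    "csp_fit",
    "csp_fit_from_covariances",
    "csp_features",
    "csp_features_from_covariances",
    "mi_rank",
    "qda_fit",
    "qda_predict",
    "loso_evaluate",
    "group_average_trials",
    "conform_epochs",
    "classify_conditions",
]

LOG_VAR_FLOOR = 1e-15


# --------------------------------------------------------------------- #
# covariances and CSP
# --------------------------------------------------------------------- #

def epoch_covariances(ep: EpochSet | np.ndarray) -> np.ndarray:
    """Per-epoch sample covariance (channels x channels, ddof=1)."""
    data = ep.data if isinstance(ep, EpochSet) else np.asarray(ep, float)
    n_t = data.shape[-1]
    centered = data - data.mean(axis=-1, keepdims=True)
    return np.einsum("eit,ejt->eij", centered, centered) / (n_t - 1)


@dataclass
class CSPModel:
    """Spatial filters ordered by discriminability.

    ``eigenvalues[i]`` is the class-A variance fraction of component ``i``
    after whitening by the composite covariance; the class-B fraction is
    its complement.
    """

    filters: np.ndarray       # (n_channels, n_components), most discriminative first
    eigenvalues: np.ndarray   # in [0, 1], aligned with filters
    component_order: np.ndarray
    regularized: bool = False


def _class_covariance(covs: np.ndarray) -> np.ndarray:
    traces = np.trace(covs, axis1=1, axis2=2)
    if (traces <= 0).any():
        raise ValueError("epoch with non-positive covariance trace")
    return (covs / traces[:, None, None]).mean(axis=0)


def csp_fit_from_covariances(covs_a: np.ndarray,
                             covs_b: np.ndarray) -> CSPModel:
    """CSP from per-epoch covariance stacks (n_epochs, ch, ch) per class."""
    if covs_a.shape[0] < 2 or covs_b.shape[0] < 2:
        raise ValueError("need at least 2 epochs per class")
    ca = _class_covariance(covs_a)
    cb = _class_covariance(covs_b)
    composite = ca + cb
    regularized = False
    eigvals = np.linalg.eigvalsh(composite)
    if eigvals[0] <= 1e-10 * eigvals[-1]:
        ridge = 1e-6 * np.trace(composite) / composite.shape[0]
        composite = composite + ridge * np.eye(composite.shape[0])
        regularized = True
        logger.info("csp_fit: rank-deficient composite covariance, "
                    "ridge %.3g applied", ridge)
    lam, vec = sla.eigh(ca, composite)
    lam = np.clip(lam, 0.0, 1.0)
    # ties in discriminability (complementary pairs) put the class-A-dominant
    # component first; rounding keeps float noise from perturbing the order
    disc = np.round(np.maximum(lam, 1.0 - lam), 10)
    order = np.lexsort((np.arange(lam.size), -np.round(lam, 10), -disc))
    return CSPModel(filters=vec[:, order], eigenvalues=lam[order],
                    component_order=order, regularized=regularized)


def csp_fit(epochs_a: EpochSet, epochs_b: EpochSet) -> CSPModel:
    """Fit CSP on two epoch sets sharing the same channels."""
    if epochs_a.channel_labels != epochs_b.channel_labels:
        raise ValueError("epoch sets must share the channel set")
    return csp_fit_from_covariances(epoch_covariances(epochs_a),
                                    epoch_covariances(epochs_b))


def csp_features_from_covariances(covs: np.ndarray, model: CSPModel,
                                  n_components: int) -> np.ndarray:
    """Log variance of each spatially filtered epoch, from covariances."""
    if n_components > model.filters.shape[1]:
        raise ValueError(
            f"requested {n_components} components, only "
            f"{model.filters.shape[1]} available")
    w = model.filters[:, :n_components]
    var = np.einsum("ci,ecd,di->ei", w, covs, w)
    n_floor = int((var <= 0).sum())
    if n_floor:
        logger.info("csp_features: %d zero-variance projections floored", n_floor)
    return np.log(np.maximum(var, LOG_VAR_FLOOR))


def csp_features(ep: EpochSet, model: CSPModel,
                 n_components: int) -> np.ndarray:
    """(n_epochs, n_components) log-variance CSP features."""
    return csp_features_from_covariances(epoch_covariances(ep), model,
                                         n_components)


# --------------------------------------------------------------------- #
# mutual-information feature ranking
# --------------------------------------------------------------------- #

@dataclass
class FeatureSelection:
    mi_bits: np.ndarray
    selected_indices: np.ndarray  # sorted by MI descending, ties by lower index

    def top(self, k: int) -> np.ndarray:
        return self.selected_indices[:k]


def _binned_mi_bits(x: np.ndarray, y01: np.ndarray, n_bins: int) -> float:
    """Plug-in mutual information (bits) between a discretized feature and
    a binary label, with equal-frequency binning."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    codes = np.searchsorted(edges, x, side="right")
    n = x.size
    joint = np.zeros((codes.max() + 1, 2))
    np.add.at(joint, (codes, y01), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def mi_rank(features: np.ndarray, labels: np.ndarray) -> FeatureSelection:
    """Rank features by mutual information with a binary label.

    Each feature is discretized into ceil(sqrt(n)) equal-frequency bins;
    the estimate is the plug-in MI of the binned joint distribution.
    Constant features score 0.
    """
    x = np.asarray(features, dtype=float)
    labs = np.asarray(labels)
    classes = np.unique(labs)
    if classes.size != 2:
        raise ValueError("mi_rank requires binary labels")
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    y01 = (labs == classes[1]).astype(int)
    n_bins = int(np.ceil(np.sqrt(x.shape[0])))
    mi = np.array([_binned_mi_bits(x[:, j], y01, n_bins)
                   for j in range(x.shape[1])])
    mi = np.maximum(mi, 0.0)
    order = np.lexsort((np.arange(mi.size), -mi))
    return FeatureSelection(mi_bits=mi, selected_indices=order)


# --------------------------------------------------------------------- #
# quadratic discriminant analysis
# --------------------------------------------------------------------- #

@dataclass
class QDAModel:
    classes: np.ndarray
    means: np.ndarray             # (n_classes, d)
    covariances: np.ndarray       # (n_classes, d, d), regularized
    priors: np.ndarray
    log_dets: np.ndarray
    precisions: np.ndarray
    shrinkage: float = 0.0


def _shrink(cov: np.ndarray, alpha: float) -> np.ndarray:
    d = cov.shape[0]
    return (1.0 - alpha) * cov + alpha * (np.trace(cov) / d) * np.eye(d)


def qda_fit(features: np.ndarray, labels: np.ndarray,
            shrinkage: float = 0.0) -> QDAModel:
    """Gaussian classifier with class-specific covariances.

    ``shrinkage`` pulls each class covariance toward a scaled identity; if
    a covariance is still singular, the minimal shrinkage that restores
    positive-definiteness is applied and logged.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.ndim == 2 and x.shape[1] == 0:
        raise ValueError("no features")
    labs = np.asarray(labels)
    classes = np.unique(labs)
    n, d = x.shape
    means, covs, priors = [], [], []
    for c in classes:
        xc = x[labs == c]
        if xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means.append(xc.mean(axis=0))
        cov = np.cov(xc, rowvar=False, ddof=1).reshape(d, d)
        cov = _shrink(cov, shrinkage)
        eig_min = np.linalg.eigvalsh(cov)[0]
        if eig_min <= 1e-12 * max(np.trace(cov) / d, 1.0):
            alpha = max(shrinkage, 1e-4)
            cov = _shrink(np.cov(xc, rowvar=False, ddof=1).reshape(d, d), alpha)
            while np.linalg.eigvalsh(cov)[0] <= 0 and alpha < 1.0:
                alpha = min(10 * alpha, 1.0)
                cov = _shrink(np.cov(xc, rowvar=False, ddof=1).reshape(d, d),
                              alpha)
            logger.info("qda_fit: singular covariance for class %r, "
                        "shrinkage raised to %.3g", c, alpha)
        covs.append(cov)
        priors.append(xc.shape[0] / n)
    covs = np.stack(covs)
    signs, log_dets = np.linalg.slogdet(covs)
    if (signs <= 0).any():
        raise ValueError("covariance not positive-definite after shrinkage")
    return QDAModel(classes=classes, means=np.stack(means), covariances=covs,
                    priors=np.asarray(priors), log_dets=log_dets,
                    precisions=np.linalg.inv(covs), shrinkage=shrinkage)


def qda_predict(model: QDAModel,
                features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and softmax posteriors.

    Discriminant per class: log prior - 0.5 log|Sigma| - 0.5 Mahalanobis^2.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n_classes = model.classes.size
    disc = np.empty((x.shape[0], n_classes))
    for i in range(n_classes):
        diff = x - model.means[i]
        maha = np.einsum("nd,de,ne->n", diff, model.precisions[i], diff)
        disc[:, i] = (np.log(model.priors[i]) - 0.5 * model.log_dets[i]
                      - 0.5 * maha)
    disc -= disc.max(axis=1, keepdims=True)
    post = np.exp(disc)
    post /= post.sum(axis=1, keepdims=True)
    return model.classes[np.argmax(disc, axis=1)], post


# --------------------------------------------------------------------- #
# the full pipeline
# --------------------------------------------------------------------- #

@dataclass
class DecoderSettings:
    """Hyperparameter grid and inner-CV layout for model selection."""

    components_grid: tuple[int, ...] = (2, 4, 6, 8)
    shrinkage_grid: tuple[float, ...] = (0.0, 0.01, 0.1)
    inner_k: int = 10
    inner_repeats: int = 3
    seed: int = 0

    def combos(self, n_channels: int):
        for m in self.components_grid:
            if m > n_channels:
                continue
            for k in range(2, m + 1):
                for a in self.shrinkage_grid:
                    yield (m, k, a)


@dataclass
class LanguageDecoder:
    """Trained CSP -> MI -> QDA pipeline for one (components, k, shrinkage)."""

    csp: CSPModel
    selection: FeatureSelection
    qda: QDAModel
    n_components: int
    k_features: int
    shrinkage: float

    @classmethod
    def fit(cls, covs: np.ndarray, labels: np.ndarray, n_components: int,
            k_features: int, shrinkage: float) -> "LanguageDecoder":
        classes = np.unique(labels)
        if classes.size != 2:
            raise ValueError("decoder requires exactly 2 classes")
        model = csp_fit_from_covariances(covs[labels == classes[0]],
                                         covs[labels == classes[1]])
        feats = csp_features_from_covariances(covs, model, n_components)
        sel = mi_rank(feats, labels)
        keep = sel.top(k_features)
        qda = qda_fit(feats[:, keep], labels, shrinkage=shrinkage)
        return cls(csp=model, selection=sel, qda=qda,
                   n_components=n_components, k_features=k_features,
                   shrinkage=shrinkage)

    def features(self, covs: np.ndarray) -> np.ndarray:
        feats = csp_features_from_covariances(covs, self.csp,
                                              self.n_components)
        return feats[:, self.selection.top(self.k_features)]

    def predict(self, covs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return qda_predict(self.qda, self.features(covs))


def _stratified_folds(labels: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Class-stratified fold index arrays (shuffled, deterministic per rng)."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _inner_cv_accuracy(covs: np.ndarray, labels: np.ndarray, combo,
                       settings: DecoderSettings,
                       rng: np.random.Generator) -> float:
    m, k_feat, alpha = combo
    accs = []
    for _ in range(settings.inner_repeats):
        for test_idx in _stratified_folds(labels, settings.inner_k, rng):
            train = np.setdiff1d(np.arange(labels.size), test_idx)
            if np.unique(labels[train]).size < 2 or test_idx.size == 0:
                continue
            try:
                dec = LanguageDecoder.fit(covs[train], labels[train],
                                          m, k_feat, alpha)
            except ValueError:
                continue
            pred, _ = dec.predict(covs[test_idx])
            accs.append(float(np.mean(pred == labels[test_idx])))
    return float(np.mean(accs)) if accs else 0.0


@dataclass
class LosoResult:
    fold_accuracy: dict
    mean: float
    sd: float
    chosen: dict  # per held-out subject: (n_components, k_features, shrinkage)
    decoders: dict


def loso_evaluate(segments: list[EpochSet],
                  settings: DecoderSettings | None = None,
                  keep_decoders: bool = False) -> LosoResult:
    """Leave-one-subject-out evaluation of the language decoder.

    ``segments`` holds one EpochSet per subject whose per-epoch ``condition``
    carries the class label (e.g. "english"/"italian").  For each held-out
    subject, the remaining subjects' segments are pooled trial-wise,
    hyperparameters are chosen by inner repeated stratified 10-fold
    accuracy, the pipeline is refit on the full pool and scored on the
    held-out subject.  Fully seeded via ``settings.seed``.
    """
    settings = settings or DecoderSettings()
    if len(segments) < 3:
        raise ValueError("need at least 3 subjects for LOSO")
    subj_ids = [str(ep.subject_id[0]) for ep in segments]
    covs = [epoch_covariances(ep) for ep in segments]
    labels = [np.asarray(ep.condition) for ep in segments]
    n_channels = segments[0].n_channels
    combos = list(settings.combos(n_channels))
    if not combos:
        raise ValueError("hyperparameter grid is empty for this channel count")

    fold_acc, chosen, decoders = {}, {}, {}
    for i, subj in enumerate(subj_ids):
        train_covs = np.concatenate([c for j, c in enumerate(covs) if j != i])
        train_labs = np.concatenate([l for j, l in enumerate(labels) if j != i])
        if np.unique(train_labs).size < 2:
            raise ValueError("a class is absent from the training pool")
        best, best_acc = None, -1.0
        for combo in combos:
            rng = np.random.default_rng(
                np.random.SeedSequence([settings.seed, i, hash(combo) & 0x7FFFFFFF]))
            acc = _inner_cv_accuracy(train_covs, train_labs, combo, settings, rng)
            if acc > best_acc + 1e-12:
                best, best_acc = combo, acc
        dec = LanguageDecoder.fit(train_covs, train_labs, *best)
        pred, _ = dec.predict(covs[i])
        fold_acc[subj] = float(np.mean(pred == labels[i]))
        chosen[subj] = best
        if keep_decoders:
            decoders[subj] = dec
    accs = np.array(list(fold_acc.values()))
    return LosoResult(fold_accuracy=fold_acc, mean=float(accs.mean()),
                      sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
                      chosen=chosen, decoders=decoders)


# --------------------------------------------------------------------- #
# condition projection
# --------------------------------------------------------------------- #

def group_average_trials(epoch_sets: list[EpochSet]) -> EpochSet:
    """Average trials across subjects channel-by-channel and sample-by-sample.

    Trials are matched across subjects by ``stimulus_id`` (the only
    defensible alignment under randomized presentation order), yielding one
    averaged trial per stimulus per condition.  Stimuli missing for some
    subjects are averaged over the subjects that have them (logged).
    """
    combined = concatenate_epochs(epoch_sets)
    n_subjects = len(epoch_sets)
    stims = list(dict.fromkeys(combined.stimulus_id))
    data, cond, stim_out = [], [], []
    for stim in stims:
        mask = combined.stimulus_id == stim
        n_avail = int(mask.sum())
        if n_avail < n_subjects:
            logger.info("group_average_trials: stimulus %s present for only "
                        "%d/%d subjects", stim, n_avail, n_subjects)
        data.append(combined.data[mask].mean(axis=0))
        cond.append(combined.condition[np.flatnonzero(mask)[0]])
        stim_out.append(stim)
    return EpochSet(
        data=np.stack(data), rate_hz=combined.rate_hz,
        time_ms=combined.time_ms.copy(),
        channel_labels=list(combined.channel_labels),
        condition=np.array(cond, dtype=object),
        subject_id=np.array(["group"] * len(stims), dtype=object),
        stimulus_id=np.array(stim_out, dtype=object),
        alignment=combined.alignment,
        info={"n_subjects_averaged": n_subjects},
    )


def conform_epochs(ep: EpochSet, n_times: int) -> EpochSet:
    """Crop (from the first post-onset sample) or reflect-pad epochs to
    the training segment length."""
    start = int(np.searchsorted(ep.time_ms, 0.0))
    if start + n_times <= ep.n_times:
        data = ep.data[:, :, start: start + n_times]
    else:
        avail = ep.n_times - start
        if avail < 2:
            raise ValueError("epochs too short to conform")
        logger.info("conform_epochs: reflect-padding %d -> %d samples",
                    avail, n_times)
        data = np.pad(ep.data[:, :, start:],
                      ((0, 0), (0, 0), (0, n_times - avail)), mode="reflect")
    time_ms = np.arange(n_times) * 1000.0 / ep.rate_hz
    out = ep.copy()
    out.data = data
    out.time_ms = time_ms
    return out


def classify_conditions(decoder: LanguageDecoder, averaged: EpochSet,
                        scale: float = 1.0) -> dict[str, dict]:
    """Project group-averaged condition trials through a trained pipeline.

    ``scale`` rescales the averaged trials before covariance extraction;
    pass sqrt(n_subjects) to restore the single-trial variance scale that
    cross-subject averaging divides by n_subjects.  Returns per-condition
    percentages of trials assigned to each language class.
    """
    covs = epoch_covariances(averaged.data * scale)
    pred, _ = decoder.predict(covs)
    out: dict[str, dict] = {}
    for cond in averaged.conditions_present():
        mask = np.asarray(averaged.condition) == cond
        n = int(mask.sum())
        n_eng = int(np.sum(pred[mask] == "english"))
        out[cond] = {
            "pct_english": 100.0 * n_eng / n,
            "pct_italian": 100.0 * (n - n_eng) / n,
            "n_trials": n,
        }
    return out
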