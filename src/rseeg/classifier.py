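"""PCA + LDA classification with random under-sampling bootstrap and LOO CV.

Features are session-averaged relative PSD values at every location
(20 channels + 10 lateralised regional averages) for every integer
frequency bin 1-40 Hz and 11 named bands: 30 x 51 = 1530 features under
the default layout.  PCA (fit once on the two groups, unsupervised)
retains the smallest number of leading components whose cumulative
explained variance exceeds 98%; a two-class LDA with a small ridge on the
within-class covariance is trained on the component scores.

Evaluation: in each of 100 bootstrap iterations the majority class is
under-sampled (without replacement) to the minority size n, and the
balanced 2n set is scored by leave-one-out cross-validation.  Per
iteration, the ROC of the LOO posteriors is interpolated onto a fixed
101-point FPR grid; the reported curve/accuracy are means over
iterations, and the AUC is the area under the mean curve.  The "apparent"
(train-on-all) ROC is reported alongside as an overfitting reference.
The final classifier averages the per-iteration LDA coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve

from .montage import MontageSpec
from .spectral import EpochPowerMatrix, session_average_relative_psd

#: band -> integer-Hz bins; the 11 bands of the default feature layout
DEFAULT_FEATURE_BANDS: dict[str, tuple[int, ...]] = {
    "delta": tuple(range(1, 4)),
    "theta": tuple(range(3, 8)),
    "alpha": tuple(range(8, 14)),
    "alpha1": tuple(range(8, 11)),
    "alpha2": tuple(range(11, 14)),
    "sigma": tuple(range(12, 16)),
    "beta": tuple(range(13, 31)),
    "beta1": tuple(range(13, 22)),
    "beta2": tuple(range(22, 31)),
    "gamma": tuple(range(30, 41)),
    "broad": tuple(range(1, 41)),
}


def build_features(
    epms: dict[str, EpochPowerMatrix],
    montage: MontageSpec,
    bands: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Subjects x features matrix of session-averaged relative PSDs.

    ``epms`` maps subject id to that subject's epoch-power matrix.  Per
    location (channel or lateralised region = mean of member channels)
    the features are the 40 relative-PSD bins plus the band means.
    Subjects missing a channel use the regional fallback implicitly
    (regions average whichever member channels are present); a subject
    missing a whole region is dropped with a warning.
    """
    if bands is None:
        bands = DEFAULT_FEATURE_BANDS
    regions = montage.regions()
    rows, index, names = [], [], []
    for sid, epm in epms.items():
        avg = session_average_relative_psd(epm)  # channels x bins
        bins = epm.bins
        loc_values: dict[str, np.ndarray] = {}
        for lab in montage.labels:
            if lab in epm.channels:
                loc_values[lab] = avg[epm.channels.index(lab)]
        for reg, members in regions.items():
            present = [loc_values[m] for m in members if m in loc_values]
            if not present:
                break
            loc_values[reg] = np.mean(present, axis=0)
        expected = len(montage.labels) + len(regions)
        if len(loc_values) != expected:
            continue  # no fallback possible: drop subject
        feats, names = [], []
        for loc in list(montage.labels) + list(regions):
            v = loc_values[loc]
            for f in bins:
                feats.append(v[int(f) - int(bins[0])])
                names.append(f"{loc}_bin{int(f)}")
            for bname, bbins in bands.items():
                cols = [int(b) - int(bins[0]) for b in bbins]
                feats.append(float(np.mean(v[cols])))
                names.append(f"{loc}_{bname}")
        rows.append(feats)
        index.append(sid)
    return pd.DataFrame(rows, index=index, columns=names)


@dataclass
class PCABasis:
    mean: np.ndarray
    components: np.ndarray  # K x features
    explained_variance_fraction: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T


def pca_reduce(X, variance_threshold: float = 0.98):
    """Scores and basis of the minimal PCA exceeding the variance threshold."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    p = PCA(svd_solver="full").fit(X)
    cum = np.cumsum(p.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_threshold) + 1)
    k = min(k, len(cum))
    basis = PCABasis(
        mean=p.mean_, components=p.components_[:k],
        explained_variance_fraction=float(cum[k - 1]),
    )
    return basis.transform(X), basis


def _fit_lda(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6):
    """Two-class LDA coefficients (w, b); posterior = sigmoid(w.x + b).

    Within-class covariance is pooled and ridged by ``ridge`` x mean
    diagonal for numerical safety; priors are equal (the bootstrap sets
    are balanced).
    """
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n = len(X)
    S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / max(n - 2, 1)
    S = S + ridge * max(np.trace(S) / S.shape[0], 1e-300) * np.eye(S.shape[0])
    w = np.linalg.solve(S, mu1 - mu0)
    b = -0.5 * float(w @ (mu0 + mu1))
    return w, b


def _posterior(w: np.ndarray, b: float, X: np.ndarray) -> np.ndarray:
    z = X @ w + b
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def auc(case_scores, control_scores) -> float:
    """Probability a random case outranks a random control; ties count 1/2."""
    case = np.asarray(case_scores, float)
    ctrl = np.asarray(control_scores, float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("need at least one score per class")
    greater = (case[:, None] > ctrl[None, :]).sum()
    ties = (case[:, None] == ctrl[None, :]).sum()
    return float((greater + 0.5 * ties) / (case.size * ctrl.size))


def _roc_on_grid(y: np.ndarray, scores: np.ndarray, grid: np.ndarray):
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    # step interpolation: best TPR attainable at FPR <= grid value
    return np.array([tpr[fpr <= g].max() if (fpr <= g).any() else 0.0
                     for g in grid])


@dataclass
class ClassifierArtifact:
    """Averaged PCA+LDA classifier and its bootstrap evaluation summary."""

    pca: PCABasis
    coef: np.ndarray           # averaged LDA weights, PCA space
    intercept: float
    class_labels: tuple[str, str]   # (control, case)
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    auc: float
    accuracy: float
    apparent_mean_tpr: np.ndarray
    apparent_auc: float
    per_subject_posterior: pd.Series
    n_iterations: int
    seed: int
    per_iteration_auc: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "pca_mean": self.pca.mean.tolist(),
            "pca_components": self.pca.components.tolist(),
            "explained_variance_fraction": self.pca.explained_variance_fraction,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "fpr_grid": self.fpr_grid.tolist(),
            "mean_tpr": self.mean_tpr.tolist(),
            "auc": self.auc,
            "accuracy": self.accuracy,
            "apparent_auc": self.apparent_auc,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierArtifact":
        pca = PCABasis(
            mean=np.array(d["pca_mean"]),
            components=np.array(d["pca_components"]),
            explained_variance_fraction=d["explained_variance_fraction"],
        )
        return cls(
            pca=pca, coef=np.array(d["coef"]), intercept=d["intercept"],
            class_labels=tuple(d["class_labels"]),
            fpr_grid=np.array(d["fpr_grid"]), mean_tpr=np.array(d["mean_tpr"]),
            auc=d["auc"], accuracy=d["accuracy"],
            apparent_mean_tpr=np.array(d["mean_tpr"]),
            apparent_auc=d["apparent_auc"],
            per_subject_posterior=pd.Series(dtype=float),
            n_iterations=d["n_iterations"], seed=d["seed"],
        )


def bootstrap_loo_evaluate(
    features: pd.DataFrame,
    labels: pd.Series,
    case_label: str,
    control_label: str,
    n_iterations: int = 100,
    variance_threshold: float = 0.98,
    seed: int = 0,
    refit_pca_per_iteration: bool = False,
) -> ClassifierArtifact:
    """Random under-sampling bootstrap with LOO-CV LDA evaluation.

    Each iteration draws ``n`` = minority-class-size subjects from the
    majority class (without replacement; every minority subject is always
    included), scores the balanced 2n set by leave-one-out, and records
    the ROC/accuracy of the held-out posteriors.  Deterministic given
    ``seed``.
    """
    labels = labels.loc[features.index]
    mask = labels.isin([case_label, control_label])
    X_all = features.loc[mask].to_numpy(dtype=float)
    y_all = (labels.loc[mask] == case_label).to_numpy().astype(int)
    ids = features.index[mask]
    if (y_all == 1).sum() < 5 or (y_all == 0).sum() < 5:
        raise ValueError("each class needs at least 5 subjects")

    Z_all, basis = pca_reduce(X_all, variance_threshold)
    rng = np.random.default_rng(seed)
    minority = int(min((y_all == 1).sum(), (y_all == 0).sum()))
    idx_case = np.flatnonzero(y_all == 1)
    idx_ctrl = np.flatnonzero(y_all == 0)

    grid = np.linspace(0.0, 1.0, 101)
    tprs, app_tprs, accs, aucs = [], [], [], []
    coefs, intercepts = [], []
    post_sum = np.zeros(len(y_all))
    post_cnt = np.zeros(len(y_all))

    for _ in range(n_iterations):
        if len(idx_case) > minority:
            take_case = rng.choice(idx_case, size=minority, replace=False)
            take_ctrl = idx_ctrl
        else:
            take_case = idx_case
            take_ctrl = rng.choice(idx_ctrl, size=minority, replace=False)
        sel = np.concatenate([take_case, take_ctrl])
        if refit_pca_per_iteration:
            Z_it, basis_it = pca_reduce(X_all[sel], variance_threshold)
            Z, y = Z_it, y_all[sel]
        else:
            Z, y = Z_all[sel], y_all[sel]

        loo_post = np.empty(len(sel))
        for i in range(len(sel)):
            keep = np.ones(len(sel), bool)
            keep[i] = False
            w, b = _fit_lda(Z[keep], y[keep])
            loo_post[i] = _posterior(w, b, Z[i:i + 1])[0]
        w_full, b_full = _fit_lda(Z, y)
        app_post = _posterior(w_full, b_full, Z)

        tprs.append(_roc_on_grid(y, loo_post, grid))
        app_tprs.append(_roc_on_grid(y, app_post, grid))
        accs.append(float(((loo_post >= 0.5) == y).mean()))
        aucs.append(auc(loo_post[y == 1], loo_post[y == 0]))
        if not refit_pca_per_iteration:
            coefs.append(w_full)
            intercepts.append(b_full)
            post_sum[sel] += loo_post
            post_cnt[sel] += 1

    mean_tpr = np.mean(tprs, axis=0)
    app_mean_tpr = np.mean(app_tprs, axis=0)
    coef = np.mean(coefs, axis=0) if coefs else np.zeros(Z_all.shape[1])
    intercept = float(np.mean(intercepts)) if intercepts else 0.0
    with np.errstate(invalid="ignore"):
        per_subject = np.where(post_cnt > 0, post_sum / np.maximum(post_cnt, 1),
                               _posterior(coef, intercept, Z_all))
    return ClassifierArtifact(
        pca=basis,
        coef=coef,
        intercept=intercept,
        class_labels=(control_label, case_label),
        fpr_grid=grid,
        mean_tpr=mean_tpr,
        auc=float(np.trapezoid(mean_tpr, grid)),
        accuracy=float(np.mean(accs)),
        apparent_mean_tpr=app_mean_tpr,
        apparent_auc=float(np.trapezoid(app_mean_tpr, grid)),
        per_subject_posterior=pd.Series(per_subject, index=ids),
        n_iterations=n_iterations,
        seed=seed,
        per_iteration_auc=np.array(aucs),
    )


def posterior_probability(
    artifact: ClassifierArtifact, features: pd.DataFrame
) -> pd.Series:
    """Case-class posterior for new subjects through the stored basis."""
    if features.shape[1] != artifact.pca.mean.shape[0]:
        raise ValueError(
            f"feature layout mismatch: {features.shape[1]} columns, "
            f"classifier expects {artifact.pca.mean.shape[0]}"
        )
    Z = artifact.pca.transform(features.to_numpy(dtype=float))
    return pd.Series(
        _posterior(artifact.coef, artifact.intercept, Z), index=features.index
    )


def assign_quadrants(p_mci: pd.Series, p_ad: pd.Series) -> pd.Series:
    """Quadrant of the (MCI probability, AD probability) plane, split at 0.5.

    Q2: both low (little or no decline); Q3: MCI high, AD low (possible
    mild decline); Q4: both high (greatest decline); Q1: AD high only.
    """
    out = {}
    for sid in p_mci.index:
        hi_m, hi_a = p_mci[sid] >= 0.5, p_ad[sid] >= 0.5
        out[sid] = {(False, False): "Q2", (True, False): "Q3",
                    (True, True): "Q4", (False, True): "Q1"}[(hi_m, hi_a)]
    return pd.Series(out)
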