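"""Orthogonal projections to latent structures discriminant analysis (OPLS-DA).

A from-scratch NIPALS implementation for two-class metabolite screening:

* orthogonal signal correction -- ``n_ortho`` components of X-variation
  orthogonal to the class variable are estimated and removed, then a single
  predictive PLS component is fitted against the (centered) 0/1 class
  vector;
* R2Y, the fraction of class-variable variance reconstructed by the
  predictive component;
* Q2Y, the leave-one-out cross-validated counterpart (the model, including
  centering/scaling, is refitted on every fold);
* VIP, variable importance in projection for the single predictive
  component, normalized so that the mean squared VIP over variables is 1;
* a label-permutation test whose regression intercepts at zero label
  correlation summarize overfitting risk;
* the differential-metabolite decision rule
  ``VIP >= 1 and (FC >= 2 or FC <= 0.5) and q <= 0.05`` with BH-adjusted
  q-values from Welch's t on log2 abundances.

Leave-one-out is the cross-validation scheme throughout, appropriate for
the six-sample two-condition design the pipeline targets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaboliteTable",
    "OplsdaModel",
    "PermutationResult",
    "fit_oplsda",
    "permutation_test",
    "screen_metabolites",
]


@dataclass
class MetaboliteTable:
    """Compound x sample abundance table with per-compound class labels."""

    abundances: pd.DataFrame  # compounds x samples, positive reals
    classes: pd.Series  # compound -> class label (anthocyanin, flavonol, ...)
    conditions: pd.Series  # sample -> condition label

    def __post_init__(self) -> None:
        self.classes = self.classes.reindex(self.abundances.index)
        self.conditions = self.conditions.reindex(self.abundances.columns)
        if self.classes.isna().any():
            raise ValueError("missing class labels for some compounds")
        if self.conditions.isna().any():
            raise ValueError("missing condition labels for some samples")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.abundances.index)

    def compounds_of_class(self, label: str) -> list[str]:
        return list(self.classes.index[self.classes == label])


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA model (1 predictive + ``n_ortho`` orthogonal comps)."""

    var_names: list[str]
    classes: tuple  # (class coded 0, class coded 1)
    scaling: str
    n_ortho: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    w_pred: np.ndarray = field(repr=False)
    p_pred: np.ndarray = field(repr=False)
    q_pred: float = 0.0
    t_pred: np.ndarray = field(repr=False, default=None)
    w_orth: np.ndarray = field(repr=False, default=None)  # (k, p)
    p_orth: np.ndarray = field(repr=False, default=None)
    t_orth: np.ndarray = field(repr=False, default=None)  # (k, n)
    r2y: float = 0.0
    q2y: float = 0.0
    vip: pd.Series = field(repr=False, default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores for new (raw-scale) observations."""
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        for k in range(self.w_orth.shape[0]):
            t_o = Xs @ self.w_orth[k]
            Xs = Xs - np.outer(t_o, self.p_orth[k])
        return Xs @ self.w_pred

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted (continuous) class value for new observations."""
        return self.transform(X) * self.q_pred + self.y_mean


def _encode_labels(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    y01 = (y == classes[1]).astype(float)
    counts = [int((y01 == v).sum()) for v in (0.0, 1.0)]
    if min(counts) < 2:
        raise ValueError(
            f"each class needs >=2 samples for leave-one-out CV, have {counts}"
        )
    return y01, tuple(classes)


def _scale_params(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "uv":
        scale = sd.copy()
    elif scaling == "pareto":
        scale = np.sqrt(sd)
    else:
        raise ValueError(f"scaling must be 'uv' or 'pareto', got {scaling!r}")
    return mean, scale


def _fit_components(Xs: np.ndarray, yc: np.ndarray, n_ortho: int):
    """Core NIPALS O-PLS on pre-scaled X and centered y (single y)."""
    X = Xs.copy()
    w = X.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("X carries no covariance with the class variable")
    w = w / norm
    w_orth_list, p_orth_list, t_orth_list = [], [], []
    for _ in range(n_ortho):
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break  # no y-orthogonal variation left
        w_o = w_o / n_o
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        w_orth_list.append(w_o)
        p_orth_list.append(p_o)
        t_orth_list.append(t_o)
    t = X @ w
    p = X.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    k = len(w_orth_list)
    pvars = Xs.shape[1]
    nobs = Xs.shape[0]
    w_orth = np.array(w_orth_list) if k else np.zeros((0, pvars))
    p_orth = np.array(p_orth_list) if k else np.zeros((0, pvars))
    t_orth = np.array(t_orth_list) if k else np.zeros((0, nobs))
    return w, p, q, t, w_orth, p_orth, t_orth


def fit_oplsda(
    X,
    y,
    n_ortho: int = 1,
    scaling: str = "uv",
    cross_validate: bool = True,
) -> OplsdaModel:
    """Fit a two-class OPLS-DA model.

    Parameters
    ----------
    X
        samples x variables matrix (array or DataFrame; DataFrame columns
        become variable names).
    y
        per-sample class labels, exactly two distinct values; the
        lexicographically larger class is coded 1.
    n_ortho
        number of y-orthogonal components removed before the single
        predictive component (0 reduces the model to 1-component PLS1).
    scaling
        "uv" (unit variance) or "pareto".

    Zero-variance variables are dropped with a warning. Q2Y is computed by
    leave-one-out unless ``cross_validate`` is False (then nan).
    """
    if isinstance(X, pd.DataFrame):
        var_names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        var_names = [f"v{i}" for i in range(Xa.shape[1])]
    y01, classes = _encode_labels(y)
    if Xa.shape[0] != y01.shape[0]:
        raise ValueError("X and y disagree on the number of samples")

    keep = Xa.std(axis=0, ddof=1) > 0
    if not keep.all():
        dropped = [v for v, k in zip(var_names, keep) if not k]
        warnings.warn(f"dropping zero-variance variables: {dropped[:5]}...", stacklevel=2)
        Xa = Xa[:, keep]
        var_names = [v for v, k in zip(var_names, keep) if k]
    if Xa.shape[1] == 0:
        raise ValueError("no variables left after zero-variance filtering")

    mean, scale = _scale_params(Xa, scaling)
    Xs = (Xa - mean) / scale
    y_mean = float(y01.mean())
    yc = y01 - y_mean

    w, p, q, t, w_orth, p_orth, t_orth = _fit_components(Xs, yc, n_ortho)
    resid = yc - t * q
    tss = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / tss

    q2y = np.nan
    if cross_validate:
        press = 0.0
        n = Xa.shape[0]
        for i in range(n):
            mask = np.arange(n) != i
            Xtr, ytr = Xa[mask], y01[mask]
            keep_f = Xtr.std(axis=0, ddof=1) > 0
            m_f, s_f = _scale_params(Xtr[:, keep_f], scaling)
            Xs_f = (Xtr[:, keep_f] - m_f) / s_f
            ym_f = float(ytr.mean())
            wf, pf, qf, _, wof, pof, _ = _fit_components(Xs_f, ytr - ym_f, n_ortho)
            x_new = (Xa[i, keep_f] - m_f) / s_f
            for k in range(wof.shape[0]):
                x_new = x_new - (x_new @ wof[k]) * pof[k]
            y_hat = float(x_new @ wf) * qf + ym_f
            press += (y01[i] - y_hat) ** 2
        q2y = 1.0 - press / tss

    # VIP for the single predictive component: sqrt(p) * |w| / ||w||
    vip_values = np.sqrt(len(var_names)) * np.abs(w) / np.linalg.norm(w)
    return OplsdaModel(
        var_names=var_names,
        classes=classes,
        scaling=scaling,
        n_ortho=n_ortho,
        x_mean=mean,
        x_scale=scale,
        y_mean=y_mean,
        w_pred=w,
        p_pred=p,
        q_pred=q,
        t_pred=t,
        w_orth=w_orth,
        p_orth=p_orth,
        t_orth=t_orth,
        r2y=r2y,
        q2y=float(q2y),
        vip=pd.Series(vip_values, index=var_names, name="vip"),
    )


@dataclass
class PermutationResult:
    """Label-permutation validation of an OPLS-DA fit.

    ``r2_intercept`` / ``q2_intercept`` are the intercepts at zero label
    correlation of least-squares lines through the permuted (|cor|, R2Y/Q2Y)
    points plus the unpermuted point at correlation 1.
    """

    n_permutations: int
    correlations: np.ndarray = field(repr=False, default=None)
    r2_values: np.ndarray = field(repr=False, default=None)
    q2_values: np.ndarray = field(repr=False, default=None)
    actual_r2: float = 0.0
    actual_q2: float = 0.0
    r2_intercept: float = 0.0
    q2_intercept: float = 0.0


def permutation_test(
    X,
    y,
    n_permutations: int = 200,
    seed: int | np.random.Generator | None = None,
    n_ortho: int = 1,
    scaling: str = "uv",
) -> PermutationResult:
    """Refit under shuffled class labels and summarize by line intercepts."""
    if n_permutations < 20:
        raise ValueError(f"n_permutations must be >= 20, got {n_permutations}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y01, _ = _encode_labels(y)
    actual = fit_oplsda(X, y, n_ortho=n_ortho, scaling=scaling)
    cors = np.empty(n_permutations)
    r2s = np.empty(n_permutations)
    q2s = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y01)
        cors[i] = abs(float(np.corrcoef(y_perm, y01)[0, 1]))
        m = fit_oplsda(X, y_perm, n_ortho=n_ortho, scaling=scaling)
        r2s[i] = m.r2y
        q2s[i] = m.q2y
    xs = np.append(cors, 1.0)
    r2_line = np.polyfit(xs, np.append(r2s, actual.r2y), 1)
    q2_line = np.polyfit(xs, np.append(q2s, actual.q2y), 1)
    return PermutationResult(
        n_permutations=n_permutations,
        correlations=cors,
        r2_values=r2s,
        q2_values=q2s,
        actual_r2=actual.r2y,
        actual_q2=actual.q2y,
        r2_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
    )


def screen_metabolites(
    table: MetaboliteTable,
    model: OplsdaModel,
    vip_min: float = 1.0,
    fc_min: float = 2.0,
    q_max: float = 0.05,
    pseudocount: float | None = None,
    baseline: str = "G2",
    contrast: str = "G8",
) -> pd.DataFrame:
    """Differential-metabolite selection: VIP, fold change and BH q gates.

    Per compound: fold change ``(mean contrast + pc) / (mean baseline + pc)``
    with ``pc`` defaulting to half the smallest nonzero abundance in the
    table; Welch's t on log2(abundance + pc); BH q-values across compounds.
    Selected iff ``vip >= vip_min`` and (``fc >= fc_min`` or
    ``fc <= 1/fc_min``) and ``q <= q_max`` (all inclusive).
    """
    missing = [c for c in table.compound_ids if c not in set(model.var_names)]
    if missing:
        raise ValueError(f"compounds absent from the fitted model: {missing[:5]}")
    ab = table.abundances
    if pseudocount is None:
        nonzero = ab.to_numpy()[ab.to_numpy() > 0]
        pseudocount = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
    a = [s for s in ab.columns if table.conditions[s] == baseline]
    b = [s for s in ab.columns if table.conditions[s] == contrast]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 samples per condition for the screen")
    fc = (ab[b].mean(axis=1) + pseudocount) / (ab[a].mean(axis=1) + pseudocount)
    log_ab = np.log2(ab + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(
            log_ab[b].to_numpy(), log_ab[a].to_numpy(), axis=1, equal_var=False
        )
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    vip = model.vip.reindex(table.compound_ids).to_numpy()
    selected = (
        (vip >= vip_min) & ((fc >= fc_min) | (fc <= 1.0 / fc_min)) & (q <= q_max)
    )
    return pd.DataFrame(
        {
            "compound_class": table.classes,
            "vip": vip,
            "fold_change": fc,
            "p_value": p,
            "q_value": q,
            "selected": selected,
        },
        index=ab.index,
    )
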