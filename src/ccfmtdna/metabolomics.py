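"""Two-group metabolomic analysis: imputation, PLS-DA, VIP, volcano, pathway impact.

The workflow mirrors the standard targeted-metabolomics pipeline for a
two-group (e.g. septic vs sham) comparison:

1. missing intensities are imputed by feature-wise k-nearest-neighbours,
2. data are log2 transformed and autoscaled (per-metabolite mean 0, unit
   sample SD),
3. a PLS-DA model (NIPALS, y coded -1/+1) separates the groups; its
   predictive quality is the leave-one-out cross-validated
   Q2 = 1 - PRESS/TSS,
4. per-metabolite VIP scores rank discriminating metabolites
   (sum of squared VIPs equals the number of metabolites by construction),
5. a volcano analysis flags metabolites with raw-scale fold change >= 1.2
   and Benjamini-Hochberg q < 0.05 (Welch t on log2 data), and
6. each pathway's fractional impact is the VIP sum of its significant
   members divided by the VIP sum of all its members, so impact lies in
   [0, 1] per pathway.

PLS-DA, LOOCV Q2, VIP, the KNN imputer, autoscaling, the volcano filter and
the pathway impact score are implemented here; only the generic statistics
(Welch t-test, BH adjustment) are delegated to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_KNN_K = 10
DEFAULT_COMPONENTS = 2
DEFAULT_FC_THRESHOLD = 1.2
DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_VIP_THRESHOLD = 1.5


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteMatrix:
    """Samples x metabolites intensity matrix with two-group labels.

    ``data`` rows are samples, columns are metabolites; ``groups`` is indexed
    like the rows and carries exactly two distinct labels, each with at least
    two samples.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.data.columns.is_unique:
            raise ValueError("metabolite names must be unique")
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        counts = self.groups.value_counts()
        if len(counts) != 2:
            raise ValueError(f"exactly two groups required, got {list(counts.index)}")
        if counts.min() < 2:
            raise ValueError("each group needs at least two samples")

    @property
    def group_labels(self) -> tuple[str, str]:
        """(reference, case) in order of first appearance in ``groups``."""
        seen = list(dict.fromkeys(self.groups))
        return seen[0], seen[1]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetaboliteMatrix":
        df = pd.read_csv(path, index_col="sample")
        groups = df.pop("group")
        return cls(data=df, groups=groups)


def _as_frame(matrix: "MetaboliteMatrix | pd.DataFrame") -> pd.DataFrame:
    return matrix.data if isinstance(matrix, MetaboliteMatrix) else matrix


# ---------------------------------------------------------------------------
# imputation and scaling
# ---------------------------------------------------------------------------

def impute_knn(matrix: MetaboliteMatrix | pd.DataFrame,
               k: int = DEFAULT_KNN_K) -> MetaboliteMatrix | pd.DataFrame:
    """Feature-wise KNN imputation of missing intensities.

    Neighbours are *metabolites*: the distance between two metabolites is the
    root-mean-square difference over samples where both are observed.  Each
    missing entry (sample i, metabolite j) becomes the mean of the k nearest
    metabolites that are observed in sample i.  Observed entries are never
    modified.  A metabolite observed at sample i but sharing no samples with
    metabolite j is not a candidate neighbour; if no candidate exists the
    metabolite's observed mean is used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    if observed.all():
        out = df.copy()
        return (MetaboliteMatrix(out, matrix.groups.copy())
                if isinstance(matrix, MetaboliteMatrix) else out)
    all_missing = ~observed.any(axis=0)
    if all_missing.any():
        names = list(df.columns[all_missing])
        raise ValueError(f"metabolites entirely missing: {names}")

    Z = np.where(observed, X, 0.0)
    M = observed.astype(float)
    # pairwise sum of squared differences over co-observed samples
    sq = (Z ** 2).T @ M
    sumsq = sq + sq.T - 2.0 * (Z.T @ Z)
    co = M.T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(sumsq, 0.0) / co)
    dist[co == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    col_means = np.nansum(Z, axis=0) / M.sum(axis=0)
    filled = X.copy()
    for i, j in zip(*np.where(~observed)):
        candidates = np.flatnonzero(observed[i] & np.isfinite(dist[j]))
        if candidates.size == 0:
            filled[i, j] = col_means[j]
            continue
        order = candidates[np.argsort(dist[j, candidates], kind="stable")]
        nearest = order[:k]
        filled[i, j] = X[i, nearest].mean()
    out = pd.DataFrame(filled, index=df.index, columns=df.columns)
    return (MetaboliteMatrix(out, matrix.groups.copy())
            if isinstance(matrix, MetaboliteMatrix) else out)


def log2_autoscale(matrix: MetaboliteMatrix | pd.DataFrame) -> pd.DataFrame:
    """log2 transform then autoscale each metabolite to mean 0, unit SD.

    The SD uses the n-1 (sample) denominator.  Requires a complete, strictly
    positive matrix; a zero-variance metabolite is an error naming it.
    """
    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    if (X <= 0).any():
        raise ValueError("non-positive intensity encountered; log2 undefined")
    L = np.log2(X)
    mean = L.mean(axis=0)
    sd = L.std(axis=0, ddof=1)
    if (sd == 0).any():
        names = list(df.columns[sd == 0])
        raise ValueError(f"zero-variance metabolites cannot be autoscaled: {names}")
    return pd.DataFrame((L - mean) / sd, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS, single response)
# ---------------------------------------------------------------------------

def _encode_groups(groups: pd.Series | Sequence) -> tuple[np.ndarray, tuple]:
    """Map two group labels to y in {-1, +1} (order of first appearance)."""
    arr = list(groups)
    seen = list(dict.fromkeys(arr))
    if len(seen) != 2:
        raise ValueError(f"exactly two groups required, got {seen}")
    y = np.where(np.asarray(arr, dtype=object) == seen[1], 1.0, -1.0)
    return y, (seen[0], seen[1])


@dataclass
class PlsdaModel:
    """Fitted PLS-DA model (NIPALS, single centred -1/+1 response).

    ``weights`` (A, p) rows are unit-norm; ``ss`` is the response sum of
    squares explained per component, the weighting used by the VIP score.
    """

    weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    ss: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    feature_names: list[str]
    group_labels: tuple = ("-1", "+1")

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Continuous prediction of the centred -1/+1 response."""
        Xd = np.asarray(_as_frame(X) if isinstance(X, (pd.DataFrame, MetaboliteMatrix)) else X,
                        dtype=float) - self.x_mean
        yhat = np.full(Xd.shape[0], self.y_mean)
        for a in range(self.n_components):
            t = Xd @ self.weights[a]
            yhat += self.y_loadings[a] * t
            Xd = Xd - np.outer(t, self.x_loadings[a])
        return yhat


def plsda_fit(X: pd.DataFrame | np.ndarray,
              groups: pd.Series | Sequence | np.ndarray,
              n_components: int = DEFAULT_COMPONENTS) -> PlsdaModel:
    """Fit PLS-DA by NIPALS deflation on the (autoscaled) data matrix.

    ``groups`` may be the two-level labels or a numeric +/-1 vector.  X and y
    are centred internally (training means are stored for prediction).
    """
    if isinstance(X, MetaboliteMatrix):
        X = X.data
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xa = np.asarray(X, dtype=float)
    n, p = Xa.shape
    garr = np.asarray(groups)
    if garr.dtype.kind in "fiu" and set(np.unique(garr)) <= {-1.0, 1.0}:
        y = garr.astype(float)
        labels = ("-1", "+1")
    else:
        y, labels = _encode_groups(groups)
    if np.unique(y).size < 2:
        raise ValueError("response is constant; PLS-DA undefined")
    if y.size != n:
        raise ValueError("groups length must match the number of samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")

    x_mean = Xa.mean(axis=0)
    y_mean = float(y.mean())
    Xd = Xa - x_mean
    yd = y - y_mean
    W = np.zeros((n_components, p))
    T = np.zeros((n, n_components))
    P = np.zeros((n_components, p))
    q = np.zeros(n_components)
    ss = np.zeros(n_components)
    a_used = 0
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pa = (Xd.T @ t) / tt
        qa = float(yd @ t) / tt
        W[a], T[:, a], P[a], q[a] = w, t, pa, qa
        ss[a] = qa ** 2 * tt  # response SS captured by component a
        Xd = Xd - np.outer(t, pa)
        yd = yd - qa * t
        a_used += 1
    if a_used == 0:
        raise ValueError("no PLS component could be extracted (X'y vanished)")
    return PlsdaModel(weights=W[:a_used], x_scores=T[:, :a_used],
                      x_loadings=P[:a_used], y_loadings=q[:a_used],
                      ss=ss[:a_used], x_mean=x_mean, y_mean=y_mean,
                      feature_names=names, group_labels=labels)


def loocv_q2(X: pd.DataFrame | np.ndarray,
             groups: pd.Series | Sequence | np.ndarray,
             n_components: int = DEFAULT_COMPONENTS) -> float:
    """Leave-one-out cross-validated Q2 = 1 - PRESS/TSS of the PLS-DA model.

    Each sample is predicted by a model refit without it; TSS is about the
    overall response mean.  Q2 near 1 indicates a reliably predictive
    separation; values near or below 0 indicate none.
    """
    if isinstance(X, MetaboliteMatrix):
        X = X.data
    Xa = np.asarray(X, dtype=float)
    n = Xa.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least three samples")
    garr = np.asarray(groups)
    if garr.dtype.kind in "fiu" and set(np.unique(garr)) <= {-1.0, 1.0}:
        y = garr.astype(float)
    else:
        y, _ = _encode_groups(groups)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        model = plsda_fit(Xa[keep], y[keep], n_components=n_components)
        yhat = model.predict(Xa[i: i + 1])[0]
        press += (y[i] - yhat) ** 2
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def vip_scores(model: PlsdaModel) -> pd.Series:
    """Variable importance in projection for every metabolite.

    VIP_j = sqrt(p * sum_a SS_a w_aj^2 / sum_a SS_a) with unit-norm weights,
    so the mean squared VIP is 1 and sum_j VIP_j^2 = p exactly.
    """
    p = model.weights.shape[1]
    w2 = model.weights ** 2
    num = (model.ss[:, None] * w2).sum(axis=0)
    vip = np.sqrt(p * num / model.ss.sum())
    return pd.Series(vip, index=model.feature_names, name="VIP")


# ---------------------------------------------------------------------------
# volcano filtering
# ---------------------------------------------------------------------------

@dataclass
class VolcanoResult:
    """Per-metabolite fold change, Welch p, BH q, and significance flags."""

    table: pd.DataFrame
    fc_threshold: float
    q_threshold: float
    control_label: str
    case_label: str

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def volcano(matrix: MetaboliteMatrix,
            fc_threshold: float = DEFAULT_FC_THRESHOLD,
            q_threshold: float = DEFAULT_Q_THRESHOLD,
            control_label: str | None = None) -> VolcanoResult:
    """Volcano analysis on a complete raw-scale matrix.

    Fold change is the raw-scale group-mean ratio case/control (control
    defaults to the group appearing first in the labels); the threshold is
    applied direction-agnostically as max(ratio, 1/ratio) >= fc_threshold
    (inclusive).  p-values come from Welch's two-sample t-test on log2
    intensities, adjusted by Benjamini-Hochberg; the q gate is strict
    (q < q_threshold).
    """
    df = matrix.data
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("volcano requires a complete matrix; impute first")
    if (X <= 0).any():
        raise ValueError("volcano requires strictly positive raw intensities")
    ref, case = matrix.group_labels
    if control_label is not None:
        if control_label not in (ref, case):
            raise ValueError(f"unknown control label {control_label!r}")
        ref = control_label
        case = [g for g in matrix.group_labels if g != ref][0]
    a = X[(matrix.groups == case).to_numpy()]
    b = X[(matrix.groups == ref).to_numpy()]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    ratio = a.mean(axis=0) / b.mean(axis=0)
    magnitude = np.maximum(ratio, 1.0 / ratio)
    pvals = stats.ttest_ind(np.log2(a), np.log2(b), axis=0, equal_var=False).pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    sig = (magnitude >= fc_threshold) & (qvals < q_threshold)
    table = pd.DataFrame({
        "fold_change": ratio,
        "fc_magnitude": magnitude,
        "p_value": pvals,
        "q_value": qvals,
        "significant": sig,
    }, index=df.columns)
    return VolcanoResult(table=table, fc_threshold=fc_threshold,
                         q_threshold=q_threshold, control_label=ref,
                         case_label=case)


# ---------------------------------------------------------------------------
# pathway fractional impact
# ---------------------------------------------------------------------------

@dataclass
class PathwayImpactResult:
    """Fractional impact per pathway plus their sum (the per-tissue total)."""

    table: pd.DataFrame
    total: float


def pathway_impact(pathways: Mapping[str, Sequence[str]], vip: pd.Series,
                   significant: Iterable[str]) -> PathwayImpactResult:
    """Fractional impact of each pathway.

    I_p = (sum of VIP over significant members of p) / (sum of VIP over all
    members of p), hence 0 when no member is significant and 1 when all are.
    The total (the per-tissue "sum of the fractional impact") is the sum of
    I_p over pathways.
    """
    sig = set(significant)
    rows = []
    for name, members in pathways.items():
        members = list(members)
        missing = [m for m in members if m not in vip.index]
        if missing:
            raise KeyError(f"pathway {name!r} members missing from VIP vector: {missing}")
        denom = float(vip[members].sum())
        if denom <= 0:
            raise ValueError(f"pathway {name!r} has zero total VIP")
        sig_members = [m for m in members if m in sig]
        num = float(vip[sig_members].sum()) if sig_members else 0.0
        rows.append({"pathway": name, "n_members": len(members),
                     "n_significant": len(sig_members), "impact": num / denom})
    table = pd.DataFrame(rows, columns=["pathway", "n_members", "n_significant",
                                        "impact"]).set_index("pathway")
    return PathwayImpactResult(table=table, total=float(table["impact"].sum()))


def significant_by_vip(vip: pd.Series,
                       threshold: float = DEFAULT_VIP_THRESHOLD) -> list[str]:
    """Metabolites with VIP strictly greater than the threshold (default 1.5).

    An alternative significance source for :func:`pathway_impact` when no
    volcano result is available.
    """
    return list(vip.index[vip > threshold])


def read_pathway_map(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (pathway, metabolite) TSV into a membership map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pathway", "metabolite"],
                     comment="#")
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.pathway), []).append(str(r.metabolite))
    return out
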