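"""Supervised disentanglement metrics and the reporting protocol.

Eight scores in three families, each normalized to [0, 1] with 1
optimal:

- intervention-based: ``z_diff`` (pair-difference classifier),
  ``z_var`` (fixed-factor variance vote), ``irs`` (interventional
  robustness);
- predictor-based: ``dci`` (disentanglement component of the
  importance-matrix analysis), ``sap`` (separated attribute
  predictability);
- information-based: ``mig`` (mutual-information gap), ``jemmig``
  (joint entropy minus MI gap), ``dcimig`` (per-dimension MI gaps
  aggregated per factor).

Reports can be computed over all generative factors or with the
position/orientation factors (and their latent dimensions) excluded,
mirroring the two evaluation protocols used for pose-aware models.

Conventions: continuous factors and latents are discretized into
equal-count bins for the intervention- and information-based metrics;
predictor-based metrics see continuous values.  A periodic orientation
factor is represented as (cos 2t, sin 2t) wherever a real-valued target
is needed, honouring the silhouette pi-ambiguity, and is binned modulo
pi otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression, Lasso
from sklearn.metrics import mutual_info_score
from sklearn.tree import DecisionTreeClassifier

METRIC_NAMES = ("z_diff", "z_var", "irs", "dci", "sap", "mig", "jemmig",
                "dcimig")
POSE_FACTORS = ("x", "y", "orientation")


@dataclass(frozen=True)
class MetricReport:
    """The eight scores, their arithmetic mean, and the protocol used."""

    scores: dict[str, float]
    average: float
    protocol: str  # "all_factors" | "excluding_position_orientation"

    def as_dict(self) -> dict:
        out = dict(self.scores)
        out["average"] = self.average
        out["protocol"] = self.protocol
        return out


@dataclass(frozen=True)
class FactorAssignment:
    """Greedy factor -> latent-dimension assignment by max |correlation|.

    Factors whose best available correlation is below the threshold stay
    unnamed (mapped to None); each dimension is assigned at most once.
    """

    mapping: dict[str, int | None]
    correlations: pd.DataFrame
    threshold: float = 0.5

    def assigned_dims(self) -> list[int]:
        return sorted({d for d in self.mapping.values() if d is not None})


# ---------------------------------------------------------------------------
# factor/latent preparation
# ---------------------------------------------------------------------------

def _factor_frame(factors) -> pd.DataFrame:
    if isinstance(factors, pd.DataFrame):
        return factors
    return pd.DataFrame(factors)


def _is_categorical(col: pd.Series) -> bool:
    return (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
            or pd.api.types.is_string_dtype(col))


def equal_count_bins(values: np.ndarray, bins: int) -> np.ndarray:
    """Discretize into (up to) ``bins`` equal-count bins; returns codes."""
    v = np.asarray(values, dtype=np.float64)
    uniq = np.unique(v)
    if len(uniq) <= bins:  # already discrete: keep the levels as-is
        return np.searchsorted(uniq, v)
    qs = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
    codes = np.searchsorted(qs, v, side="right")
    # re-index to consecutive codes in case of duplicate quantiles
    _, codes = np.unique(codes, return_inverse=True)
    return codes


def discretize_factors(factors, bins: int = 10,
                       periodic: tuple[str, ...] = ("orientation",)
                       ) -> tuple[np.ndarray, list[str]]:
    """Integer-coded factor matrix (n, K) and the factor names kept.

    Categorical columns keep their categories; periodic columns are
    binned modulo pi; other columns get equal-count bins.  Factors with
    a single observed level are dropped with a warning (no information
    to disentangle).
    """
    tab = _factor_frame(factors)
    cols, names = [], []
    for name in tab.columns:
        col = tab[name]
        if _is_categorical(col):
            codes = pd.Categorical(col).codes.astype(int)
        elif name in periodic:
            codes = equal_count_bins(np.mod(col.to_numpy(float), math.pi), bins)
        else:
            codes = equal_count_bins(col.to_numpy(float), bins)
        if len(np.unique(codes)) < 2:
            warnings.warn(f"factor {name!r} has a single observed level; "
                          "excluded from metrics")
            continue
        cols.append(codes)
        names.append(name)
    if not cols:
        raise ValueError("no usable factors remain")
    return np.stack(cols, axis=1), names


def _continuous_targets(factors, periodic=("orientation",)
                        ) -> list[tuple[str, np.ndarray, bool]]:
    """Per factor: (name, target matrix (n, t), is_categorical).

    Periodic factors expand to the two columns (cos 2t, sin 2t); their
    per-dimension scores are averaged back into one factor score by the
    callers.
    """
    tab = _factor_frame(factors)
    out = []
    for name in tab.columns:
        col = tab[name]
        if _is_categorical(col):
            out.append((name, pd.Categorical(col).codes[:, None], True))
        elif name in periodic:
            t = col.to_numpy(float)
            out.append((name, np.stack([np.cos(2 * t), np.sin(2 * t)], axis=1),
                        False))
        else:
            out.append((name, col.to_numpy(float)[:, None], False))
    return out


def _normalize_latents(latents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(latents, dtype=np.float64)
    std = z.std(axis=0)
    active = std > 1e-9
    zn = np.where(active, (z - z.mean(axis=0)) / np.where(active, std, 1.0), 0.0)
    return zn, active


# ---------------------------------------------------------------------------
# intervention-based metrics
# ---------------------------------------------------------------------------

def intervention_metrics(latents, factors, *, bins: int = 10,
                         n_votes: int = 600, pairs_per_vote: int = 32,
                         seed: int = 0) -> dict[str, float]:
    """z_diff, z_var and irs.

    All three fix (or intervene on) generative factors and watch the
    latent response: z_diff classifies which factor was held fixed from
    the mean absolute latent difference of matched pairs; z_var votes
    for the latent dimension with the smallest variance under a fixed
    factor; irs measures how little each dimension moves when only
    non-target factors change.
    """
    rng = np.random.default_rng(seed)
    F, names = discretize_factors(factors, bins=bins)
    zn, active = _normalize_latents(np.asarray(latents, dtype=np.float64))
    n, L = zn.shape
    K = F.shape[1]
    if n < 4 * bins:
        raise ValueError("too few samples per fixed-factor group")

    groups = [[np.flatnonzero(F[:, k] == v) for v in np.unique(F[:, k])]
              for k in range(K)]

    # ---- z_diff ---------------------------------------------------------
    feats = np.zeros((n_votes, L))
    labels = np.zeros(n_votes, dtype=int)
    for t in range(n_votes):
        k = rng.integers(K)
        g = groups[k][rng.integers(len(groups[k]))]
        i = g[rng.integers(len(g), size=pairs_per_vote)]
        j = g[rng.integers(len(g), size=pairs_per_vote)]
        feats[t] = np.abs(zn[i] - zn[j]).mean(axis=0)
        labels[t] = k
    half = n_votes // 2
    clf = LogisticRegression(max_iter=500)
    clf.fit(feats[:half], labels[:half])
    z_diff = float(clf.score(feats[half:], labels[half:]))

    # ---- z_var ----------------------------------------------------------
    votes = np.zeros((n_votes, 2), dtype=int)
    act_idx = np.flatnonzero(active)
    for t in range(n_votes):
        k = rng.integers(K)
        g = groups[k][rng.integers(len(groups[k]))]
        sub = g[rng.integers(len(g), size=min(len(g), 64))]
        var = zn[sub].var(axis=0)
        d = act_idx[np.argmin(var[act_idx])] if len(act_idx) else 0
        votes[t] = (d, k)
    table = np.zeros((L, K))
    for d, k in votes[:half]:
        table[d, k] += 1
    dim_to_factor = np.argmax(table, axis=1)
    correct = sum(dim_to_factor[d] == k for d, k in votes[half:])
    z_var = float(correct / (n_votes - half))

    # ---- irs ------------------------------------------------------------
    irs = _irs_score(zn, F, diff_quantile=0.99)
    return {"z_diff": z_diff, "z_var": z_var, "irs": irs}


def _irs_score(zn: np.ndarray, F: np.ndarray, diff_quantile: float = 0.99
               ) -> float:
    """Interventional robustness: for each latent dimension, how stable
    it stays when the factor it tracks is fixed and the others vary."""
    n, L = zn.shape
    K = F.shape[1]
    global_dev = np.abs(zn - zn.mean(axis=0)).max(axis=0)
    global_dev[global_dev == 0] = 1.0
    R = np.zeros((L, K))
    for k in range(K):
        devs = np.zeros(L)
        weight = 0
        for v in np.unique(F[:, k]):
            g = np.flatnonzero(F[:, k] == v)
            if len(g) < 2:
                continue
            mu = zn[g].mean(axis=0)
            d = np.quantile(np.abs(zn[g] - mu), diff_quantile, axis=0)
            devs += len(g) * d
            weight += len(g)
        if weight:
            R[:, k] = 1.0 - (devs / weight) / global_dev
    per_dim = R.max(axis=1)
    w = zn.var(axis=0)
    if w.sum() == 0:
        return 0.0
    return float(np.clip((per_dim * w).sum() / w.sum(), 0.0, 1.0))


# ---------------------------------------------------------------------------
# predictor-based metrics
# ---------------------------------------------------------------------------

def predictor_metrics(latents, factors, *, bins: int = 10, seed: int = 0,
                      dci_predictor: str = "forest") -> dict[str, float]:
    """dci (disentanglement component) and sap."""
    z = np.asarray(latents, dtype=np.float64)
    n, L = z.shape
    targets = _continuous_targets(factors)
    K = len(targets)

    # ---- dci importance matrix -----------------------------------------
    P = np.zeros((L, K))
    for k, (name, y, cat) in enumerate(targets):
        imps = np.zeros(L)
        for t in range(y.shape[1]):
            if dci_predictor == "forest":
                if cat:
                    est = RandomForestClassifier(n_estimators=20, max_depth=8,
                                                 random_state=seed + k)
                else:
                    est = RandomForestRegressor(n_estimators=20, max_depth=8,
                                                random_state=seed + k)
                est.fit(z, y[:, t].ravel())
                imps += est.feature_importances_
            elif dci_predictor == "lasso":
                zs = (z - z.mean(0)) / np.where(z.std(0) > 0, z.std(0), 1.0)
                est = Lasso(alpha=0.01, max_iter=5000)
                est.fit(zs, y[:, t].astype(float).ravel())
                imps += np.abs(est.coef_)
            else:
                raise ValueError("dci_predictor must be 'forest' or 'lasso'")
        P[:, k] = imps / y.shape[1]
    dci = _dci_disentanglement(P)

    # ---- sap ------------------------------------------------------------
    Fd, names = discretize_factors(factors, bins=bins)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tr, te = order[: n // 2], order[n // 2:]
    sap_gaps = []
    for k in range(Fd.shape[1]):
        yk = Fd[:, k]
        chance = np.bincount(yk[te]).max() / len(te)
        # the single-feature tree needs enough leaves for every level
        depth = max(3, int(np.ceil(np.log2(yk.max() + 1))) + 1)
        scores = np.zeros(L)
        for d in range(L):
            tree = DecisionTreeClassifier(max_depth=depth, random_state=seed)
            tree.fit(z[tr, d:d + 1], yk[tr])
            acc = tree.score(z[te, d:d + 1], yk[te])
            scores[d] = max(0.0, (acc - chance) / (1.0 - chance + 1e-12))
        top2 = np.sort(scores)[-2:]
        sap_gaps.append(top2[1] - top2[0] if L > 1 else top2[-1])
    sap = float(np.clip(np.mean(sap_gaps), 0.0, 1.0))
    return {"dci": float(dci), "sap": sap}


def _dci_disentanglement(P: np.ndarray) -> float:
    """Entropy-based disentanglement score of an importance matrix."""
    L, K = P.shape
    total = P.sum()
    if total <= 0:
        return 0.0
    D = np.zeros(L)
    for i in range(L):
        row = P[i]
        s = row.sum()
        if s <= 0:
            continue
        p = row / s
        h = -(p[p > 0] * np.log(p[p > 0])).sum() / math.log(K) if K > 1 else 0.0
        D[i] = 1.0 - h
    rho = P.sum(axis=1) / total
    return float(np.clip((rho * D).sum(), 0.0, 1.0))


# ---------------------------------------------------------------------------
# information-based metrics
# ---------------------------------------------------------------------------

def _entropy(codes: np.ndarray) -> float:
    p = np.bincount(codes) / len(codes)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def information_metrics(latents, factors, *, bins: int = 10
                        ) -> dict[str, float]:
    """mig, jemmig and dcimig from binned mutual information (nats)."""
    z = np.asarray(latents, dtype=np.float64)
    n, L = z.shape
    F, names = discretize_factors(factors, bins=bins)
    K = F.shape[1]
    Zd = np.stack([equal_count_bins(z[:, d], bins) for d in range(L)], axis=1)

    MI = np.zeros((L, K))
    for d in range(L):
        for k in range(K):
            MI[d, k] = mutual_info_score(Zd[:, d], F[:, k])
    Hf = np.array([_entropy(F[:, k]) for k in range(K)])

    # mig: normalized gap between the two largest MI values per factor
    mig_terms = []
    jemmig_terms = []
    for k in range(K):
        order = np.argsort(MI[:, k])[::-1]
        top, second = (MI[order[0], k],
                       MI[order[1], k] if L > 1 else 0.0)
        mig_terms.append((top - second) / Hf[k] if Hf[k] > 0 else 0.0)
        # joint entropy with the best dimension
        joint = _entropy(Zd[:, order[0]] * (F[:, k].max() + 1) + F[:, k])
        jem = joint - top + second
        norm = Hf[k] + math.log(bins)
        jemmig_terms.append(1.0 - jem / norm if norm > 0 else 0.0)
    mig = float(np.clip(np.mean(mig_terms), 0.0, 1.0))
    jemmig = float(np.clip(np.mean(jemmig_terms), 0.0, 1.0))

    # dcimig: per-dimension gaps, aggregated per factor
    gains = np.zeros(K)
    for d in range(L):
        order = np.argsort(MI[d])[::-1]
        gap = MI[d, order[0]] - (MI[d, order[1]] if K > 1 else 0.0)
        k = order[0]
        gains[k] = max(gains[k], gap)
    dcimig = float(np.clip(gains.sum() / Hf.sum(), 0.0, 1.0)) if Hf.sum() > 0 else 0.0
    return {"mig": mig, "jemmig": jemmig, "dcimig": dcimig}


# ---------------------------------------------------------------------------
# factor identification and the report
# ---------------------------------------------------------------------------

def _correlation_ratio(codes: np.ndarray, z: np.ndarray) -> float:
    """eta: sqrt of the between-group variance fraction (categorical)."""
    var = z.var()
    if var == 0:
        return 0.0
    between = 0.0
    for v in np.unique(codes):
        g = z[codes == v]
        between += len(g) * (g.mean() - z.mean()) ** 2
    return float(math.sqrt(between / (len(z) * var)))


def circular_correlation(a, b, *, period: float = math.pi,
                         max_n: int = 3000, seed: int = 0) -> float:
    """Fisher–Lee T-linear circular–circular association of two angle sets.

    Angles are rescaled so one ``period`` spans the full circle (the
    default, pi, treats both variables as axial, honouring the
    second-moment orientation ambiguity).  The pairwise form

        r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) /
            sqrt(sum sin^2(a_i - a_j) * sum sin^2(b_i - b_j))

    is used rather than the mean-centred variant, which is unstable for
    near-uniform angle distributions (the circular mean direction is
    then arbitrary).  Subsamples to ``max_n`` points for the O(n^2)
    pair sums.
    """
    a = np.asarray(a, dtype=np.float64) * (2 * math.pi / period)
    b = np.asarray(b, dtype=np.float64) * (2 * math.pi / period)
    if len(a) != len(b):
        raise ValueError("angle arrays must have equal length")
    if len(a) > max_n:
        idx = np.random.default_rng(seed).choice(len(a), max_n, replace=False)
        a, b = a[idx], b[idx]
    da = np.sin(a[:, None] - a[None, :])
    db = np.sin(b[:, None] - b[None, :])
    denom = math.sqrt((da ** 2).sum() * (db ** 2).sum())
    if denom == 0:
        return 0.0
    return float((da * db).sum() / denom)


def _circular_linear_corr(theta2: np.ndarray, z: np.ndarray) -> float:
    """Mardia circular-linear correlation of z with the doubled angle."""
    c, s = np.cos(theta2), np.sin(theta2)
    if z.std() == 0:
        return 0.0
    rc = np.corrcoef(z, c)[0, 1]
    rs = np.corrcoef(z, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    denom = 1.0 - rcs ** 2
    if denom <= 0:
        return 0.0
    r2 = (rc ** 2 + rs ** 2 - 2 * rc * rs * rcs) / denom
    return float(math.sqrt(max(0.0, r2)))


def identify_factor_dims(latents, factors, *, threshold: float = 0.5,
                         periodic: tuple[str, ...] = ("orientation",)
                         ) -> FactorAssignment:
    """Match factors to latent dimensions by maximum |correlation|.

    Linear factors use |Pearson r| (affine-invariant), periodic factors
    the circular-linear correlation against the doubled angle, and
    categorical factors the correlation ratio.  A factor whose best
    available correlation is below ``threshold`` stays unnamed; exact
    ties resolve toward the lower dimension index; each dimension is
    assigned at most once (greedy, strongest correlation first).
    """
    z = np.asarray(latents, dtype=np.float64)
    n, L = z.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    tab = _factor_frame(factors)
    corr = pd.DataFrame(0.0, index=tab.columns,
                        columns=[f"z{d}" for d in range(L)])
    for name in tab.columns:
        col = tab[name]
        for d in range(L):
            zd = z[:, d]
            if zd.std() == 0:
                corr.loc[name, f"z{d}"] = 0.0
                continue
            if _is_categorical(col):
                r = _correlation_ratio(pd.Categorical(col).codes, zd)
            elif name in periodic:
                r = _circular_linear_corr(2.0 * col.to_numpy(float), zd)
            else:
                f = col.to_numpy(float)
                r = abs(np.corrcoef(f, zd)[0, 1]) if f.std() > 0 else 0.0
            corr.loc[name, f"z{d}"] = r
    mapping: dict[str, int | None] = {name: None for name in tab.columns}
    taken: set[int] = set()
    # strongest correlations claim their dimension first
    cands = sorted(
        ((corr.loc[name, f"z{d}"], d, name)
         for name in tab.columns for d in range(L)),
        key=lambda t: (-t[0], t[1]))
    for r, d, name in cands:
        if r < threshold:
            break
        if mapping[name] is None and d not in taken:
            mapping[name] = d
            taken.add(d)
    return FactorAssignment(mapping=mapping, correlations=corr,
                            threshold=threshold)


def metric_report(latents, factors, protocol: str = "all_factors", *,
                  bins: int = 10, seed: int = 0,
                  assignment: FactorAssignment | None = None,
                  pose_dims: tuple[int, ...] | None = None) -> MetricReport:
    """All eight scores plus their average under one protocol.

    ``protocol="excluding_position_orientation"`` drops the pose factors
    (x, y, orientation) and their latent dimensions — taken from
    ``pose_dims`` if given (e.g. the model's z_equi columns), otherwise
    from a correlation-based :class:`FactorAssignment` (computed here if
    not supplied).
    """
    z = np.asarray(latents, dtype=np.float64)
    tab = _factor_frame(factors).reset_index(drop=True)
    if protocol == "excluding_position_orientation":
        keep_f = [c for c in tab.columns if c not in POSE_FACTORS]
        if not keep_f:
            raise ValueError("no factors remain after excluding pose")
        if pose_dims is None:
            if assignment is None:
                assignment = identify_factor_dims(z, tab)
            pose_dims = tuple(d for f, d in assignment.mapping.items()
                              if f in POSE_FACTORS and d is not None)
        keep_d = [d for d in range(z.shape[1]) if d not in set(pose_dims)]
        if not keep_d:
            raise ValueError("no latent dimensions remain after excluding pose")
        z = z[:, keep_d]
        tab = tab[keep_f]
    elif protocol != "all_factors":
        raise ValueError(f"unknown protocol {protocol!r}")

    scores = {}
    scores.update(intervention_metrics(z, tab, bins=bins, seed=seed))
    scores.update(predictor_metrics(z, tab, bins=bins, seed=seed))
    scores.update(information_metrics(z, tab, bins=bins))
    scores = {k: float(np.clip(scores[k], 0.0, 1.0)) for k in METRIC_NAMES}
    avg = float(np.mean([scores[k] for k in METRIC_NAMES]))
    return MetricReport(scores=scores, average=avg, protocol=protocol)


def select_best_run(reports: list[MetricReport]) -> MetricReport:
    """The multi-seed selection rule: keep the run with the highest
    total (equivalently, average) score."""
    if not reports:
        raise ValueError("no reports given")
    return max(reports, key=lambda r: r.average)
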