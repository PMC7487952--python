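"""Validation statistics: diagnostic accuracy, weighted kappa, suppression.

The agreement statistic is Cohen's weighted kappa for k ordered categories:

    kappa_w = (sum_ij w_ij p_ij - sum_ij w_ij p_i. p_.j)
              / (1 - sum_ij w_ij p_i. p_.j)

with linear (Cicchetti-Allison) weights ``w_ij = 1 - |i-j|/(k-1)`` by
default or quadratic (Fleiss-Cohen) weights ``1 - ((i-j)/(k-1))^2``. For
k = 2 both reduce to the unweighted Cohen's kappa. The asymptotic standard
error is the Fleiss-Cohen-Everitt (1969) large-sample form; a seeded
multinomial bootstrap is available as a cross-check.

Undefined quantities (zero denominators, degenerate tables) are flagged,
never reported as 0 or 1. Small-cell suppression masks reported counts at
or below a threshold and turns affected percentages into one-sided bounds,
mirroring de-identification practice for claims warehouses; masking applies
only at reporting, never to internal computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


# ---------------------------------------------------------------------------
# 2x2 diagnostic accuracy


@dataclass(frozen=True)
class MetricResult:
    """Se/Sp/PPV/NPV with their counts; None where the denominator is 0."""

    tp: int
    fp: int
    tn: int
    fn: int
    label: str = ""
    flags: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)


def confusion_2x2(claims: Sequence[bool], reference: Sequence[bool],
                  label: str = "") -> MetricResult:
    """Cross-classify paired boolean labels (missing filtered upstream)."""
    c = np.asarray(claims, dtype=bool)
    r = np.asarray(reference, dtype=bool)
    if c.size == 0 or c.shape != r.shape:
        raise ValueError("need >= 1 complete pair of labels")
    tp = int((c & r).sum())
    fp = int((c & ~r).sum())
    tn = int((~c & ~r).sum())
    fn = int((~c & r).sum())
    flags = []
    if tp + fn == 0:
        flags.append("sensitivity_undefined")
    if tn + fp == 0:
        flags.append("specificity_undefined")
    if tp + fp == 0:
        flags.append("ppv_undefined")
    if tn + fn == 0:
        flags.append("npv_undefined")
    return MetricResult(tp, fp, tn, fn, label=label, flags=tuple(flags))


# ---------------------------------------------------------------------------
# k x k agreement


@dataclass(frozen=True)
class AgreementTable:
    """Observed k x k cross-classification; rows = claims, cols = reference.

    Categories with zero marginals are retained so k stays scheme-fixed.
    """

    observed: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        O = np.asarray(self.observed)
        if O.ndim != 2 or O.shape[0] != O.shape[1]:
            raise ValueError("observed must be square")
        if (O < 0).any() or not np.issubdtype(O.dtype, np.integer):
            raise ValueError("observed must hold non-negative integers")
        object.__setattr__(self, "observed", O)
        if self.labels and len(self.labels) != O.shape[0]:
            raise ValueError("labels length must equal k")

    @property
    def k(self) -> int:
        return self.observed.shape[0]

    @property
    def n(self) -> int:
        return int(self.observed.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def expected(self) -> np.ndarray:
        """E_ij = row_i * col_j / N (marginal independence)."""
        return np.outer(self.row_marginals, self.col_marginals) / self.n


def agreement_table(claims_levels: Sequence[int], ref_levels: Sequence[int],
                    k: int, labels: Sequence[str] = ()) -> AgreementTable:
    """Build the observed table from paired category indices in 0..k-1."""
    c = np.asarray(claims_levels, dtype=int)
    r = np.asarray(ref_levels, dtype=int)
    if c.size == 0:
        raise ValueError("no comparable pairs")
    if c.shape != r.shape:
        raise ValueError("paired label arrays must have equal length")
    if ((c < 0) | (c >= k) | (r < 0) | (r >= k)).any():
        raise ValueError("labels outside 0..k-1 (mixed schemes?)")
    O = np.zeros((k, k), dtype=int)
    np.add.at(O, (c, r), 1)
    return AgreementTable(O, tuple(labels))


def kappa_weights(k: int, scheme: str = "linear") -> np.ndarray:
    """Agreement-weight matrix: W_ii = 1, off-diagonal partial credit."""
    if scheme not in ("linear", "quadratic"):
        raise ValueError("scheme must be 'linear' or 'quadratic'")
    if k == 1:
        return np.ones((1, 1))
    i, j = np.indices((k, k))
    d = np.abs(i - j) / (k - 1)
    return 1.0 - (d if scheme == "linear" else d ** 2)


@dataclass(frozen=True)
class KappaResult:
    kappa: Optional[float]
    scheme: str = "linear"
    se: Optional[float] = None
    ci_level: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    flags: tuple[str, ...] = ()

    @property
    def band(self) -> Optional[str]:
        """Conventional interpretation bands (0.40 / 0.75 cutpoints)."""
        if self.kappa is None:
            return None
        if self.kappa > 0.75:
            return "excellent"
        if self.kappa >= 0.40:
            return "fair_to_good"
        return "poor"


def _kappa_terms(p: np.ndarray, W: np.ndarray):
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float((W * p).sum())
    pe = float((W * np.outer(row, col)).sum())
    return row, col, po, pe


def kappa_from_joint(p: np.ndarray, scheme: str = "linear") -> float:
    """Weighted kappa implied by a joint probability matrix (the analytic
    counterpart used to check simulated worlds)."""
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    _, _, po, pe = _kappa_terms(p, kappa_weights(p.shape[0], scheme))
    if np.isclose(pe, 1.0):
        raise ValueError("degenerate joint distribution")
    return (po - pe) / (1.0 - pe)


def weighted_kappa(table: AgreementTable, scheme: str = "linear") -> KappaResult:
    """Point estimate; degenerate tables (all weighted mass expected) are
    flagged undefined rather than returning 0/0."""
    if table.n < 1:
        raise ValueError("empty table")
    W = kappa_weights(table.k, scheme)
    p = table.observed / table.n
    _, _, po, pe = _kappa_terms(p, W)
    if np.isclose(pe, 1.0):
        return KappaResult(None, scheme, flags=("degenerate_table",))
    return KappaResult((po - pe) / (1.0 - pe), scheme)


def _asymptotic_se(table: AgreementTable, scheme: str, kappa: float) -> float:
    """Fleiss-Cohen-Everitt large-sample standard error of weighted kappa."""
    W = kappa_weights(table.k, scheme)
    p = table.observed / table.n
    row, col, po, pe = _kappa_terms(p, W)
    wbar_i = W @ col          # row-wise weighted average against col marginals
    wbar_j = row @ W          # col-wise against row marginals
    term = (W - (wbar_i[:, None] + wbar_j[None, :]) * (1.0 - kappa)) ** 2
    var = ((p * term).sum() - (kappa - pe * (1.0 - kappa)) ** 2) \
        / (table.n * (1.0 - pe) ** 2)
    return float(np.sqrt(max(var, 0.0)))


def kappa_ci(table: AgreementTable, scheme: str = "linear",
             level: float = 0.95, method: str = "asymptotic",
             n_boot: int = 2000, seed: int = 0) -> KappaResult:
    """Confidence interval for weighted kappa, truncated to [-1, 1].

    ``asymptotic`` uses the normal interval with the Fleiss-Cohen-Everitt
    variance; ``bootstrap`` is a seeded multinomial percentile interval
    over resampled pairs.
    """
    if method not in ("asymptotic", "bootstrap"):
        raise ValueError("method must be 'asymptotic' or 'bootstrap'")
    if table.n < 2:
        raise ValueError("need N >= 2 for an interval")
    point = weighted_kappa(table, scheme)
    if point.kappa is None:
        return point
    flags = list(point.flags)
    if table.n < 30:
        flags.append("small_sample_asymptotics")
    if method == "asymptotic":
        se = _asymptotic_se(table, scheme, point.kappa)
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        lo, hi = point.kappa - z * se, point.kappa + z * se
    else:
        rng = np.random.default_rng(seed)
        probs = (table.observed / table.n).ravel()
        draws = rng.multinomial(table.n, probs, size=n_boot)
        W = kappa_weights(table.k, scheme)
        ks = []
        for d in draws:
            p = d.reshape(table.k, table.k) / table.n
            _, _, po, pe = _kappa_terms(p, W)
            if not np.isclose(pe, 1.0):
                ks.append((po - pe) / (1.0 - pe))
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(ks, [alpha, 1.0 - alpha])
        se = float(np.std(ks, ddof=1))
    if lo >= hi - 1e-15:
        flags.append("degenerate_interval")
    return KappaResult(point.kappa, scheme, se, level,
                       float(np.clip(lo, -1.0, 1.0)),
                       float(np.clip(hi, -1.0, 1.0)), tuple(flags))


def per_level_metrics(table: AgreementTable) -> list[MetricResult]:
    """One-vs-rest collapse of the k x k table, ordered by level.

    A level with zero reference marginal has no sensitivity ("not
    calculated"); the analogous holds for the other denominators.
    """
    out = []
    O = table.observed
    total = table.n
    for L in range(table.k):
        tp = int(O[L, L])
        fp = int(O[L, :].sum() - tp)
        fn = int(O[:, L].sum() - tp)
        tn = int(total - tp - fp - fn)
        label = table.labels[L] if table.labels else str(L)
        flags = []
        if tp + fn == 0:
            flags.append("sensitivity_not_calculated")
        if tn + fp == 0:
            flags.append("specificity_not_calculated")
        if tp + fp == 0:
            flags.append("ppv_not_calculated")
        if tn + fn == 0:
            flags.append("npv_not_calculated")
        out.append(MetricResult(tp, fp, tn, fn, label=label, flags=tuple(flags)))
    return out


# ---------------------------------------------------------------------------
# small-cell suppression (reporting layer only)

MASK = "*"


def _metric_display(num: Optional[int], comp: Optional[int],
                    threshold: int) -> str:
    """Render num/(num+comp) as a percent, a one-sided bound when a count
    is masked, or NC when undefined."""
    if num is None and comp is None:
        return MASK
    if num is not None and comp is not None:
        if num + comp == 0:
            return "NC"
        return f"{100.0 * num / (num + comp):.0f}"
    if num is None:                     # numerator masked: upper bound
        return f"<{100.0 * threshold / (threshold + comp):.0f}" if comp else MASK
    return f">{100.0 * num / (num + threshold):.0f}"   # complement masked


def suppress_small_cells(result: MetricResult, threshold: int = 10) -> dict:
    """Masked reporting view of one 2x2 result.

    Counts <= ``threshold`` are replaced by a marker; a percentage whose
    numerator (or denominator complement) is masked becomes a one-sided
    bound, e.g. ">82". Internal computation is never masked.
    """
    def cnt(x: int) -> Optional[int]:
        return None if x <= threshold else x

    tp, fp, tn, fn = cnt(result.tp), cnt(result.fp), cnt(result.tn), cnt(result.fn)
    return {
        "label": result.label,
        "tp": MASK if tp is None else tp,
        "fp": MASK if fp is None else fp,
        "tn": MASK if tn is None else tn,
        "fn": MASK if fn is None else fn,
        "sensitivity": _metric_display(tp, fn, threshold),
        "specificity": _metric_display(tn, fp, threshold),
        "ppv": _metric_display(tp, fp, threshold),
        "npv": _metric_display(tn, fn, threshold),
    }
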