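"""Longitudinal nonparametric inference.

Three stages mirror the analysis design:

1. global mean PLI, T1 vs T2, one Wilcoxon signed-ranks test per band;
2. per-network per-band Wilcoxon tests with Benjamini-Hochberg false
   discovery rate control applied *within each band's family*;
3. post hoc: only (band, network) cells surviving FDR are rank-correlated
   (Kendall tau-b) against the six cognitive-domain delta scores.

Sign convention: the reported z is negative when T2 exceeds T1 on average
(the convention of classic statistical packages for paired rank tests).
The normal-approximation variance is tie-corrected and carries no continuity
correction; p-values default to the exact sign-flip distribution for
n <= 15 paired differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "StatReport",
    "wilcoxon_signed_rank",
    "fdr_per_band",
    "kendall_tau",
    "run_full_inference",
]


@dataclass
class PairedTestResult:
    """One paired T1-vs-T2 test for a (band, network) cell."""

    band: str
    network: str  # "global" for whole-matrix tests
    n: int
    z_statistic: float
    p_value: float
    method: str = "exact"
    p_fdr: float | None = None
    fdr_significant: bool = False


@dataclass
class CorrelationResult:
    """Post hoc Kendall tau between a connectivity change and a domain delta."""

    band: str
    network: str
    domain: str
    n: int
    tau: float
    p_value: float


@dataclass
class StatReport:
    """Full three-stage inference output."""

    global_tests: list[PairedTestResult] = field(default_factory=list)
    network_tests: list[PairedTestResult] = field(default_factory=list)
    correlations: list[CorrelationResult] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def paired_frame(self) -> pd.DataFrame:
        rows = [
            (r.band, r.network, r.n, r.z_statistic, r.p_value, r.method,
             r.p_fdr, r.fdr_significant)
            for r in self.global_tests + self.network_tests
        ]
        return pd.DataFrame(
            rows,
            columns=["band", "network", "n", "z", "p", "method", "p_fdr",
                     "fdr_significant"],
        )

    def correlation_frame(self) -> pd.DataFrame:
        rows = [
            (r.band, r.network, r.domain, r.n, r.tau, r.p_value)
            for r in self.correlations
        ]
        return pd.DataFrame(
            rows, columns=["band", "network", "domain", "n", "tau", "p"]
        )


def _exact_signflip_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p of W+ under the 2**n equiprobable sign assignments.

    Dynamic programming over doubled ranks (so tied average ranks become
    integers) — equivalent to exhaustive enumeration of all sign vectors.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    mu = total / 2.0
    dev = abs(2 * w_plus - mu)
    support = np.arange(total + 1, dtype=float)
    return float(dist[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(
    t1,
    t2,
    method: str = "auto",
    zero_method: str = "drop",
    band: str = "",
    network: str = "",
) -> PairedTestResult:
    """Wilcoxon signed-ranks test of T2 vs T1 on subject-aligned values.

    Zero differences are dropped (Wilcoxon's original rule; ``pratt`` keeps
    them in the ranking but excludes them from the rank sums).  Tied absolute
    differences get average ranks, and the normal-approximation variance is
    tie-corrected.  ``method``: ``"exact"`` (sign-flip distribution),
    ``"approx"`` (normal), or ``"auto"`` (exact for n <= 15).
    """
    a = np.asarray(t1, dtype=float)
    b = np.asarray(t2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("T1 and T2 must be subject-aligned, equal-length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = b[keep] - a[keep]
    if d.size < 5:
        raise ValueError(f"need >= 5 paired values, got {d.size}")

    if zero_method not in ("drop", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    nonzero = d != 0
    if not nonzero.any():
        warnings.warn("all paired differences are zero; degenerate test")
        return PairedTestResult(band, network, int(d.size), 0.0, 1.0, "degenerate")
    if zero_method == "drop":
        d = d[nonzero]
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all
        signs = d > 0
    else:  # pratt: rank zeros too, then discard their ranks
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        signs = d[d != 0] > 0

    n = ranks.size
    w_plus = float(ranks[signs].sum())
    mu = float(ranks.sum()) / 2.0  # = n(n+1)/4 when no zeros are kept
    # tie-corrected variance of W+ under random sign flips: sum(r^2)/4
    sigma2 = float(np.sum(ranks**2)) / 4.0
    z_raw = (w_plus - mu) / np.sqrt(sigma2)
    z_report = -z_raw  # T2 > T1 on average -> negative z

    if method == "auto":
        method = "exact" if n <= 15 else "approx"
    if method == "exact":
        p = _exact_signflip_p(ranks, w_plus)
    elif method == "approx":
        p = float(2 * sps.norm.sf(abs(z_raw)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairedTestResult(band, network, n, float(z_report), min(p, 1.0), method)


def fdr_per_band(
    results: list[PairedTestResult], q: float = 0.05
) -> list[PairedTestResult]:
    """Benjamini-Hochberg step-up at level ``q`` within each band's family.

    Families are formed per band and never pooled across bands; adjusted
    p-values and significance flags are written back onto the results.
    """
    by_band: dict[str, list[PairedTestResult]] = {}
    for r in results:
        by_band.setdefault(r.band, []).append(r)
    for group in by_band.values():
        ps = [r.p_value for r in group]
        reject, p_adj, _, _ = multipletests(ps, alpha=q, method="fdr_bh")
        for r, rej, pa in zip(group, reject, p_adj):
            r.fdr_significant = bool(rej)
            r.p_fdr = float(pa)
    return results


def kendall_tau(
    x,
    y,
    band: str = "",
    network: str = "",
    domain: str = "",
) -> CorrelationResult:
    """Kendall tau-b rank correlation with two-sided p.

    Missing pairs are dropped pairwise; the p-value is exact for n <= 10
    when the data are tie-free, otherwise the tie-corrected normal
    approximation is used.  A constant input leaves tau undefined (NaN).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must be aligned and equal-length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 5:
        raise ValueError(f"need >= 5 complete pairs, got {n}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant input: tau undefined")
        return CorrelationResult(band, network, domain, n, float("nan"), float("nan"))
    tie_free = len(np.unique(a)) == n and len(np.unique(b)) == n
    method = "exact" if (n <= 10 and tie_free) else "asymptotic"
    res = sps.kendalltau(a, b, variant="b", method=method)
    return CorrelationResult(
        band, network, domain, n, float(res.statistic), float(res.pvalue)
    )


def _paired_values(summary: pd.DataFrame, band: str, network: str):
    """Subject-aligned (T1, T2, subjects) mean-PLI vectors for one cell."""
    cell = summary[(summary["band"] == band) & (summary["network"] == network)]
    pivot = cell.pivot(index="subject", columns="timepoint", values="mean_pli")
    pivot = pivot.dropna(subset=["T1", "T2"])
    return pivot["T1"].to_numpy(), pivot["T2"].to_numpy(), pivot.index.to_numpy()


def run_full_inference(
    rsn_summaries: pd.DataFrame,
    cognitive_deltas: pd.DataFrame | None = None,
    alpha: float = 0.05,
    q: float = 0.05,
    method: str = "auto",
    domains=None,
) -> StatReport:
    """The full three-stage analysis.

    Parameters
    ----------
    rsn_summaries
        Tidy table (subject, timepoint, band, network, mean_pli); rows with
        network ``"global"`` feed stage 1, the rest stage 2.
    cognitive_deltas
        Per-subject domain delta scores (column ``subject`` + one column per
        domain).  Subjects missing cognition are excluded from stage 3 only.
    """
    report = StatReport(meta={"alpha": alpha, "q": q, "method": method})
    bands = list(dict.fromkeys(rsn_summaries["band"]))
    networks = [
        n for n in dict.fromkeys(rsn_summaries["network"]) if n != "global"
    ]

    # stage 1: global PLI per band (its own 6-test family)
    if (rsn_summaries["network"] == "global").any():
        for band in bands:
            t1, t2, _ = _paired_values(rsn_summaries, band, "global")
            report.global_tests.append(
                wilcoxon_signed_rank(t1, t2, method=method, band=band, network="global")
            )
        # the global tests form their own single family across bands
        ps = [r.p_value for r in report.global_tests]
        reject, p_adj, _, _ = multipletests(ps, alpha=q, method="fdr_bh")
        for r, rej, pa in zip(report.global_tests, reject, p_adj):
            r.fdr_significant = bool(rej)
            r.p_fdr = float(pa)

    # stage 2: per-network per-band, FDR per band
    for band in bands:
        for network in networks:
            t1, t2, _ = _paired_values(rsn_summaries, band, network)
            report.network_tests.append(
                wilcoxon_signed_rank(t1, t2, method=method, band=band, network=network)
            )
    fdr_per_band(report.network_tests, q=q)

    # stage 3: post hoc tau for FDR-surviving cells only
    if cognitive_deltas is not None:
        if domains is None:
            domains = [c for c in cognitive_deltas.columns
                       if c not in ("subject", "overall")]
        deltas = cognitive_deltas.set_index("subject")
        for r in report.network_tests:
            if not r.fdr_significant:
                continue
            t1, t2, subjects = _paired_values(rsn_summaries, r.band, r.network)
            dpli = pd.Series(t2 - t1, index=subjects)
            common = dpli.index.intersection(deltas.index)
            for domain in domains:
                report.correlations.append(
                    kendall_tau(
                        dpli.loc[common],
                        deltas.loc[common, domain],
                        band=r.band,
                        network=r.network,
                        domain=domain,
                    )
                )
        report.meta["n_stage3_subjects"] = (
            int(len(common)) if report.correlations else 0
        )
    return report
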