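"""Neuropsychological scoring: raw subtests -> domain z-scores -> delta scores.

z-scores are anchored to the first-timepoint (T1) group: for each measure the
T1 group mean and SD are frozen and reused at T2, so a T2 z-score of 1 means
"one baseline-group SD above the baseline-group mean".  The delta score
z(T2) - z(T1) quantifies longitudinal change; positive = improvement.

Six domains are covered by default: executive functioning, verbal memory,
working memory, information processing, attention and psychomotor speed.
Timed subtests (lower raw score = better) carry a polarity flag and are
sign-flipped before standardization.  A subtest mapped to several domains
contributes its standardized score to each; a domain fed by several subtests
takes the mean of their standardized scores.  Subjects missing a timepoint
stay explicitly missing — nothing is imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "DomainMap",
    "CognitiveTable",
    "load_battery_config",
    "default_battery",
    "domain_scores",
    "zscore_t1_anchored",
    "delta_scores",
    "load_reference_deltas",
]

T1, T2 = "T1", "T2"


@dataclass(frozen=True)
class DomainMap:
    """Subtest name -> (domains it measures, polarity)."""

    domains: tuple[str, ...]
    subtests: dict  # name -> {"domains": [...], "higher_is_better": bool}

    def __post_init__(self) -> None:
        for name, body in self.subtests.items():
            if not body.get("domains"):
                raise ValueError(f"subtest {name!r} maps to no domain")
            unknown = [d for d in body["domains"] if d not in self.domains]
            if unknown:
                raise ValueError(f"subtest {name!r} maps to unknown domains {unknown}")
        covered = {d for b in self.subtests.values() for d in b["domains"]}
        empty = [d for d in self.domains if d not in covered]
        if empty:
            raise ValueError(f"domains with no subtest: {empty}")

    def subtests_for(self, domain: str) -> list[str]:
        return [s for s, b in self.subtests.items() if domain in b["domains"]]

    def polarity(self, subtest: str) -> float:
        return 1.0 if self.subtests[subtest]["higher_is_better"] else -1.0


@dataclass
class CognitiveTable:
    """Subject x domain scores plus the frozen T1 baseline statistics."""

    scores: pd.DataFrame  # columns: subject, timepoint, <domain...>
    baseline_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    kind: str = "z"  # "raw" | "z" | "delta"


def load_battery_config(path) -> DomainMap:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return DomainMap(domains=tuple(raw["domains"]), subtests=raw["subtests"])


def default_battery() -> DomainMap:
    """The shipped six-domain battery configuration."""
    res = resources.files("megrsn.data") / "cognitive_battery.yaml"
    with resources.as_file(res) as p:
        return load_battery_config(p)


def _t1_standardize(table: pd.DataFrame, cols) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize columns against the T1 group; returns (z table, stats)."""
    t1 = table[table["timepoint"] == T1]
    stats_rows = []
    out = table.copy()
    for c in cols:
        mu = t1[c].mean()
        sd = t1[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero or undefined T1 SD for {c!r}; cannot z-score")
        out[c] = (table[c] - mu) / sd
        stats_rows.append((c, mu, sd))
    stats = pd.DataFrame(stats_rows, columns=["measure", "t1_mean", "t1_sd"])
    return out, stats


def domain_scores(
    raw: pd.DataFrame,
    dmap: DomainMap | None = None,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Aggregate raw subtest scores into per-domain scores.

    Each subtest is polarity-corrected, standardized against the T1 group,
    and averaged into every domain it measures.  The ``overall`` column is
    the mean of *all* standardized subtests (a documented convention — the
    aggregation rule behind published overall scores is not recoverable, and
    this table's overall may differ from other conventions).
    """
    dmap = dmap or default_battery()
    mapped = [s for s in dmap.subtests if s in raw.columns]
    unmapped = [
        c for c in raw.columns
        if c not in ("subject", "timepoint") and c not in dmap.subtests
    ]
    if unmapped:
        warnings.warn(f"unmapped subtest columns ignored: {unmapped}")
    missing = [s for s in dmap.subtests if s not in raw.columns]
    if missing:
        log.warning("subtests absent from table: %s", missing)

    flipped = raw.copy()
    for s in mapped:
        flipped[s] = raw[s] * dmap.polarity(s)
    z, _ = _t1_standardize(flipped, mapped)

    out = z[["subject", "timepoint"]].copy()
    for domain in dmap.domains:
        subs = [s for s in dmap.subtests_for(domain) if s in mapped]
        if not subs:
            raise ValueError(f"domain {domain!r} has no available subtest")
        out[domain] = z[subs].mean(axis=1)
    if include_overall:
        out["overall"] = z[mapped].mean(axis=1)
    return out


def zscore_t1_anchored(domains: pd.DataFrame) -> CognitiveTable:
    """z-score per-domain scores against the T1 group mean and SD.

    The same (frozen) T1 mean and SD standardize both timepoints, so T1
    z-scores have group mean 0 and SD 1 per domain by construction.
    """
    cols = [c for c in domains.columns if c not in ("subject", "timepoint")]
    if (domains["timepoint"] == T1).sum() < 2:
        raise ValueError("need >= 2 subjects at T1 to define baseline statistics")
    z, stats = _t1_standardize(domains, cols)
    return CognitiveTable(scores=z, baseline_stats=stats, kind="z")


def delta_scores(table: CognitiveTable) -> CognitiveTable:
    """Per-subject, per-domain delta = z(T2) - z(T1); positive = improvement.

    Subjects lacking either timepoint get an all-missing row (logged), never
    an imputed one.
    """
    z = table.scores
    cols = [c for c in z.columns if c not in ("subject", "timepoint")]
    t1 = z[z["timepoint"] == T1].set_index("subject")[cols]
    t2 = z[z["timepoint"] == T2].set_index("subject")[cols]
    subjects = t1.index.union(t2.index, sort=False)
    delta = t2.reindex(subjects) - t1.reindex(subjects)
    incomplete = delta.index[delta.isna().all(axis=1)].tolist()
    if incomplete:
        log.info("subjects missing a timepoint, deltas set missing: %s", incomplete)
    out = delta.reset_index()
    return CognitiveTable(scores=out, baseline_stats=table.baseline_stats, kind="delta")


def load_reference_deltas() -> pd.DataFrame:
    """The bundled reference delta-score table of the ten-patient surgical
    cohort (two subjects lack the follow-up assessment and are missing)."""
    res = resources.files("megrsn.data") / "reference_cognitive_deltas.csv"
    with resources.as_file(res) as p:
        return pd.read_csv(p)
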