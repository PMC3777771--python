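"""Cortical ROI registry, resting-state-network (RSN) definitions and
per-subject RSN connectivity summaries.

The default registry holds the 78 cortical regions of the automated
anatomical labelling (AAL) parcellation that remain after removing the six
subcortical structures per hemisphere.  Four RSNs ship as defaults — the
default mode network (DMN), left and right frontoparietal networks (FPN) and
the executive control network (ECN) — but network membership is *data*:
the YAML configuration file is authoritative and user-extensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityMatrix, mean_pli

__all__ = [
    "RoiRegistry",
    "RsnDefinition",
    "load_rsn_config",
    "default_rsn_config",
    "summarize_rsns",
    "realign",
]


@dataclass(frozen=True)
class RoiRegistry:
    """Ordered, unique ROI labels with hemisphere suffixes (``_L``/``_R``)."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("registry labels must be unique")
        if len(self.labels) < 2:
            raise ValueError("registry needs at least 2 labels")

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels


@dataclass(frozen=True)
class RsnDefinition:
    """A named resting-state network: a subset of registry labels whose
    within-subset connections define the network."""

    name: str
    members: tuple[str, ...]
    hemisphere: str | None = None  # "L"/"R" for lateralized networks

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(self.members) < 2:
            raise ValueError(f"network {self.name!r} needs >= 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"network {self.name!r} has duplicate members")
        if self.hemisphere is not None:
            bad = [m for m in self.members if not m.endswith(f"_{self.hemisphere}")]
            if bad:
                raise ValueError(
                    f"network {self.name!r} is {self.hemisphere}-lateralized but "
                    f"members {bad} lack the _{self.hemisphere} suffix"
                )

    def validate_against(self, registry: RoiRegistry) -> None:
        unknown = [m for m in self.members if m not in registry]
        if unknown:
            raise ValueError(
                f"network {self.name!r} references labels not in the "
                f"registry: {unknown}"
            )


def load_rsn_config(path) -> tuple[RoiRegistry, list[RsnDefinition]]:
    """Parse a registry + RSN YAML file and validate every membership.

    The file holds a ``registry`` label list and a ``networks`` mapping of
    name -> {members: [...], hemisphere: L|R (optional)}.  Unknown labels,
    duplicate network names, and empty memberships are rejected with the
    offending network named.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "registry" not in raw or "networks" not in raw:
        raise ValueError(f"{path}: expected 'registry' and 'networks' sections")
    registry = RoiRegistry(tuple(raw["registry"]))
    networks: list[RsnDefinition] = []
    seen: set[str] = set()
    for name, body in raw["networks"].items():
        if name in seen:
            raise ValueError(f"duplicate network name {name!r}")
        seen.add(name)
        if not body or not body.get("members"):
            raise ValueError(f"network {name!r} has no members")
        net = RsnDefinition(
            name=name,
            members=tuple(body["members"]),
            hemisphere=body.get("hemisphere"),
        )
        net.validate_against(registry)
        networks.append(net)
    return registry, networks


def default_rsn_config() -> tuple[RoiRegistry, list[RsnDefinition]]:
    """The shipped 78-ROI registry and four default RSNs."""
    path = resources.files("megrsn.data") / "rsn_default.yaml"
    with resources.as_file(path) as p:
        return load_rsn_config(p)


def realign(matrix: ConnectivityMatrix, labels) -> ConnectivityMatrix:
    """Reorder a connectivity matrix's rows/columns to a target label order."""
    labels = tuple(labels)
    if set(labels) != set(matrix.roi_labels):
        raise ValueError("realign target must be a permutation of matrix labels")
    pos = {lab: i for i, lab in enumerate(matrix.roi_labels)}
    idx = np.array([pos[lab] for lab in labels])
    return ConnectivityMatrix(
        roi_labels=labels,
        values=matrix.values[np.ix_(idx, idx)],
        band=matrix.band,
        n_epochs_averaged=matrix.n_epochs_averaged,
    )


def summarize_rsns(
    matrices,
    networks: list[RsnDefinition],
    include_global: bool = False,
) -> pd.DataFrame:
    """Tidy per-(subject, timepoint, band, network) mean-PLI table.

    Parameters
    ----------
    matrices
        Iterable of ``(subject, timepoint, ConnectivityMatrix)`` records; the
        band is read from each matrix's tag.  All matrices must share one
        label ordering — a mismatch is an error, never silently reindexed
        (use :func:`realign` explicitly).
    include_global
        Also emit a ``"global"`` row per (subject, timepoint, band): the mean
        over *all* unordered ROI pairs.
    """
    records = list(matrices)
    if not records:
        raise ValueError("no matrices given")
    ref_labels = records[0][2].roi_labels
    rows = []
    for subject, timepoint, mat in records:
        if mat.roi_labels != ref_labels:
            raise ValueError(
                f"label-order mismatch for subject {subject!r} {timepoint!r}; "
                "realign matrices explicitly before summarizing"
            )
        band_name = mat.band.name if mat.band is not None else "unspecified"
        if include_global:
            rows.append((subject, timepoint, band_name, "global", mean_pli(mat)))
        for net in networks:
            rows.append(
                (subject, timepoint, band_name, net.name, mean_pli(mat, net.members))
            )
    return pd.DataFrame(
        rows, columns=["subject", "timepoint", "band", "network", "mean_pli"]
    )
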