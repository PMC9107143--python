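"""Domain types and arm-level data handling for evidence networks of trials.

An evidence network consists of interventions coded ``1..K`` (code 1 is the
reference, "usual care" in the packaged networks) and studies contributing
arm-level binary counts (events / sample size per arm).  Counts are carried as
floats throughout: cluster-randomised studies enter with effective
(design-effect adjusted) sample sizes such as ``46.86/57.96``.

Two networks of home-safety interventions for children under five ship with
the package: uptake of safe storage of household products (poison prevention,
15 studies, 7 interventions) and possession of a fitted stair gate (falls
prevention, 12 studies, 7 interventions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Intervention",
    "Arm",
    "Study",
    "Network",
    "ContrastEstimate",
    "NetworkFormatError",
    "NetworkValidationError",
    "NetworkConnectivityError",
    "load_network",
    "write_network",
    "load_poison_network",
    "load_stair_gates_network",
    "continuity_correct",
    "apply_continuity_correction",
    "cluster_adjust",
    "log_odds_ratio",
    "study_contrast_estimates",
]

DESIGNS = ("RCT", "NRCT", "clusterRCT", "clusterNRCT")

_QUALITY_COLUMNS = ("alloc_concealment", "blinding", "followup", "confounders")

_REQUIRED_COLUMNS = ("study_id", "study_name", "design", "intervention", "events", "size")


class NetworkFormatError(ValueError):
    """The CSV is malformed (missing columns, unparsable values)."""


class NetworkValidationError(ValueError):
    """A value violates a domain invariant (e.g. events > size)."""


class NetworkConnectivityError(ValueError):
    """The comparison graph of the network is not connected."""


@dataclass(frozen=True)
class Intervention:
    code: int
    label: str

    def __post_init__(self) -> None:
        if self.code < 1:
            raise NetworkValidationError(f"intervention code must be >= 1, got {self.code}")


@dataclass(frozen=True)
class Arm:
    """One study arm: intervention code, events r and sample size n."""

    intervention: int
    events: float
    size: float

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise NetworkValidationError(f"arm size must be positive, got {self.size}")
        if not 0 <= self.events <= self.size:
            raise NetworkValidationError(
                f"events must lie in [0, size]: events={self.events}, size={self.size}"
            )

    @property
    def proportion(self) -> float:
        return self.events / self.size

    def has_zero_cell(self) -> bool:
        return self.events == 0 or self.events == self.size


@dataclass(frozen=True)
class Study:
    study_id: int
    name: str
    design: str
    arms: tuple[Arm, ...]
    quality_flags: Mapping[str, str] = field(default_factory=dict)
    cluster_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise NetworkValidationError(
                f"study {self.study_id}: unknown design {self.design!r}; expected one of {DESIGNS}"
            )
        if len(self.arms) < 2:
            raise NetworkValidationError(f"study {self.study_id}: needs >= 2 arms")
        codes = [a.intervention for a in self.arms]
        if len(set(codes)) != len(codes):
            raise NetworkValidationError(
                f"study {self.study_id}: duplicate intervention codes {codes}"
            )

    @property
    def treatments(self) -> tuple[int, ...]:
        """Intervention codes in this study, ascending (first is the baseline arm)."""
        return tuple(sorted(a.intervention for a in self.arms))

    def arm_for(self, code: int) -> Arm:
        for a in self.arms:
            if a.intervention == code:
                return a
        raise KeyError(f"study {self.study_id} has no arm with intervention {code}")

    def has_zero_cell(self) -> bool:
        return any(a.has_zero_cell() for a in self.arms)


@dataclass(frozen=True)
class Network:
    interventions: tuple[Intervention, ...]
    studies: tuple[Study, ...]
    outcome_label: str = ""

    def __post_init__(self) -> None:
        codes = sorted(i.code for i in self.interventions)
        if codes != list(range(1, len(codes) + 1)):
            raise NetworkValidationError(f"intervention codes must be contiguous from 1, got {codes}")
        known = set(codes)
        for s in self.studies:
            for a in s.arms:
                if a.intervention not in known:
                    raise NetworkValidationError(
                        f"study {s.study_id} uses unknown intervention code {a.intervention}"
                    )
        g = self.graph()
        if len(self.studies) and not nx.is_connected(g):
            parts = [sorted(c) for c in nx.connected_components(g)]
            raise NetworkConnectivityError(f"comparison graph is disconnected: components {parts}")

    @property
    def n_interventions(self) -> int:
        return len(self.interventions)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def graph(self) -> nx.Graph:
        """Comparison graph: nodes = intervention codes, edges = within-study pairs."""
        g = nx.Graph()
        g.add_nodes_from(i.code for i in self.interventions)
        for s in self.studies:
            t = s.treatments
            for i in range(len(t)):
                for j in range(i + 1, len(t)):
                    g.add_edge(t[i], t[j])
        return g

    def label(self, code: int) -> str:
        for i in self.interventions:
            if i.code == code:
                return i.label
        raise KeyError(code)

    def study(self, study_id: int) -> Study:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(f"no study with id {study_id}")

    def observed_contrasts(self) -> list[tuple[int, int]]:
        """Distinct within-study treatment pairs (c, k), c < k, sorted."""
        pairs: set[tuple[int, int]] = set()
        for s in self.studies:
            t = s.treatments
            for i in range(len(t)):
                for j in range(i + 1, len(t)):
                    pairs.add((t[i], t[j]))
        return sorted(pairs)

    def direct_studies(self, contrast: tuple[int, int]) -> list[Study]:
        c, k = sorted(contrast)
        return [s for s in self.studies if c in s.treatments and k in s.treatments]


@dataclass(frozen=True)
class ContrastEstimate:
    """A normal summary of one data point on the log odds ratio scale.

    ``estimate`` is the log OR of ``treatments[1]`` versus ``treatments[0]``.
    """

    id: str
    treatments: tuple[int, int]
    estimate: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise NetworkValidationError(f"variance must be positive, got {self.variance}")

    def flipped(self) -> "ContrastEstimate":
        c, k = self.treatments
        return ContrastEstimate(self.id, (k, c), -self.estimate, self.variance)


# ---------------------------------------------------------------------------
# Data preparation


def continuity_correct(events: float, size: float) -> tuple[float, float]:
    """Haldane–Anscombe correction for one arm: 0.5 to each cell of the 2x2.

    Equivalently events + 0.5 and size + 1.  Apply to *all* arms of a study
    that has any zero cell (events = 0 or events = size in some arm).
    """
    if events < 0 or size < 0:
        raise NetworkValidationError("events and size must be non-negative")
    return events + 0.5, size + 1.0


def apply_continuity_correction(network: Network) -> Network:
    """Return a network where every zero-cell study has all arms corrected."""
    studies = []
    for s in network.studies:
        if s.has_zero_cell():
            arms = tuple(Arm(a.intervention, *continuity_correct(a.events, a.size)) for a in s.arms)
            studies.append(replace(s, arms=arms))
        else:
            studies.append(s)
    return replace(network, studies=tuple(studies))


def cluster_adjust(
    events: float, size: float, mean_cluster_size: float, icc: float
) -> tuple[float, float]:
    """Effective-sample-size adjustment for cluster randomisation.

    Divides both cells by the design effect ``DEFF = 1 + (m - 1) * ICC`` so the
    observed proportion is preserved while the information content is deflated.
    """
    if not 0 <= icc < 1:
        raise NetworkValidationError(f"icc must be in [0, 1), got {icc}")
    if mean_cluster_size < 1:
        raise NetworkValidationError(f"mean cluster size must be >= 1, got {mean_cluster_size}")
    deff = 1.0 + (mean_cluster_size - 1.0) * icc
    return events / deff, size / deff


def log_odds_ratio(arm_c: Arm, arm_k: Arm, id: str = "") -> ContrastEstimate:
    """Delta-method log odds ratio of ``arm_k`` versus ``arm_c``.

    estimate = log[(r_k/(n_k - r_k)) / (r_c/(n_c - r_c))],
    variance = 1/r_k + 1/(n_k - r_k) + 1/r_c + 1/(n_c - r_c).

    Zero cells must have been continuity-corrected before this point.
    """
    for a in (arm_c, arm_k):
        if a.has_zero_cell():
            raise ZeroDivisionError(
                "zero cell in 2x2 table: apply the continuity correction first"
            )
    rc, nc = arm_c.events, arm_c.size
    rk, nk = arm_k.events, arm_k.size
    est = math.log((rk / (nk - rk)) / (rc / (nc - rc)))
    var = 1 / rk + 1 / (nk - rk) + 1 / rc + 1 / (nc - rc)
    return ContrastEstimate(id, (arm_c.intervention, arm_k.intervention), est, var)


def study_contrast_estimates(network: Network) -> list[ContrastEstimate]:
    """Per-study log OR summaries (continuity-corrected where needed).

    Each non-baseline arm is summarised against the study's baseline
    (lowest-coded) arm; for the packaged two-arm networks this is one estimate
    per study, with id equal to the study id.
    """
    network = apply_continuity_correction(network)
    out: list[ContrastEstimate] = []
    for s in network.studies:
        codes = s.treatments
        base = s.arm_for(codes[0])
        for code in codes[1:]:
            ident = str(s.study_id) if len(codes) == 2 else f"{s.study_id}:{code}"
            out.append(log_odds_ratio(base, s.arm_for(code), id=ident))
    return out


# ---------------------------------------------------------------------------
# CSV I/O


def load_network(
    path: str | Path,
    outcome_label: str = "",
    labels: Mapping[int, str] | None = None,
) -> Network:
    """Read a network from CSV (one row per study arm).

    Required columns: study_id, study_name, design, intervention, events, size.
    Optional: cluster_adjusted plus free-form quality columns
    (alloc_concealment, blinding, followup, confounders).
    """
    try:
        df = pd.read_csv(path, dtype={"study_name": str, "design": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise NetworkFormatError(f"cannot read network CSV {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkFormatError(f"missing required column(s): {missing}")
    labels = dict(labels or {})
    studies = []
    for sid, rows in df.groupby("study_id", sort=True):
        arms = tuple(
            Arm(int(r.intervention), float(r.events), float(r.size))
            for r in rows.itertuples(index=False)
        )
        first = rows.iloc[0]
        flags = {
            c: str(first[c])
            for c in _QUALITY_COLUMNS
            if c in df.columns and pd.notna(first[c])
        }
        studies.append(
            Study(
                study_id=int(sid),
                name=str(first.study_name),
                design=str(first.design),
                arms=arms,
                quality_flags=flags,
                cluster_adjusted=bool(first.get("cluster_adjusted", 0)),
            )
        )
    codes = sorted({a.intervention for s in studies for a in s.arms})
    interventions = tuple(Intervention(c, labels.get(c, f"Intervention {c}")) for c in codes)
    return Network(interventions=interventions, studies=tuple(studies), outcome_label=outcome_label)


def write_network(network: Network, path: str | Path) -> None:
    """Write a network back to the CSV schema accepted by :func:`load_network`."""
    rows = []
    for s in network.studies:
        for a in s.arms:
            row = {
                "study_id": s.study_id,
                "study_name": s.name,
                "design": s.design,
                "intervention": a.intervention,
                "events": a.events,
                "size": a.size,
                "cluster_adjusted": int(s.cluster_adjusted),
            }
            row.update(s.quality_flags)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged networks

POISON_LABELS: dict[int, str] = {
    1: "Usual care (UC)",
    2: "Education (E)",
    3: "Education + Free/low cost equipment (E + FE)",
    4: "Education + Equipment + Home safety inspection (E + EQ + HSI)",
    5: "Education + Equipment (E + EQ)",
    6: "Education + Equipment + Home safety inspection + Fitting (E + EQ + HSI + F)",
    7: "Free/low cost equipment (FE only)",
}

STAIR_GATE_LABELS: dict[int, str] = {
    1: "Usual care (UC)",
    2: "Education (E)",
    3: "Education + Free/low cost equipment (E + FE)",
    4: "Education + Free/low cost equipment + Home safety inspection (E + FE + HSI)",
    5: "Education + Free/low cost equipment + Fitting (E + FE + F)",
    6: "Education + Free/low cost equipment + Fitting + Home safety inspection (E + FE + F + HSI)",
    7: "Education + Home safety inspection (E + HSI)",
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("thresholdnma").joinpath("data", name)))


def load_poison_network() -> Network:
    """Safe storage of other household products (poison prevention): 15 studies, 7 interventions."""
    return load_network(
        _data_path("poison_safe_storage.csv"),
        outcome_label="Safe storage of other household products",
        labels=POISON_LABELS,
    )


def load_stair_gates_network() -> Network:
    """Possession of a fitted stair gate (falls prevention): 12 studies, 7 interventions."""
    return load_network(
        _data_path("stair_gates.csv"),
        outcome_label="Possession of a fitted stair gate",
        labels=STAIR_GATE_LABELS,
    )
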