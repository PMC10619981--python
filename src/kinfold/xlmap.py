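"""Crosslink parsing, contact grouping, chain assignment and validation.

BS3 is a lysine-lysine crosslinker with a theoretical maximum span of about
24 A between linked residues; an identified crosslink is therefore a distance
restraint.  On a homodimer the mass spectrometer cannot tell which chain a
linked residue came from, so each crosslink is assigned to the chain
combination that minimizes the anchor-atom distance before it is scored
against the distance limit.  Contacts are binned into the interaction groups
characteristic of the folded motor: within the motor domain, motor-to-tail
(including the C-terminal end of CC4), motor-to-CC2, and within the stalk.
"""

from __future__ import annotations

import importlib.resources
import itertools
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyReportError, ParseError, SchemaError, SiteLookupError
from .structmodel import StructureModel

DEFAULT_EVALUE_THRESHOLD = 0.01
DEFAULT_DISTANCE_THRESHOLD = 24.0  # A, BS3 theoretical limit

CONTACT_GROUPS = (
    "motor_intra",
    "motor_tail",
    "motor_cc2",
    "stalk_intra",
    "other",
    "interprotein",
)

_STALK_DOMAINS = {"cc2", "cc3a", "cc3b", "cc4"}
_TAIL_LIKE_DOMAINS = {"cc4", "tail"}  # motor<->CC4 C-terminus groups with motor-tail


@dataclass(frozen=True)
class CrosslinkRecord:
    """One identified lysine-lysine crosslink between two sequence positions."""

    protein_a: str
    site_a: int
    protein_b: str
    site_b: int
    evalue: float
    source_row: int = 0
    target_distance: float | None = None  # known/simulated distance, if any

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if self.site_a < 1 or self.site_b < 1:
            raise ValueError("sites are 1-based and must be >= 1")

    @property
    def unordered_key(self) -> tuple:
        ends = sorted([(self.protein_a, self.site_a), (self.protein_b, self.site_b)])
        return tuple(ends[0]) + tuple(ends[1])


class DomainMap:
    """Named half-open residue intervals per protein."""

    def __init__(self, intervals: Mapping[str, Mapping[str, Sequence[int]]]):
        self._domains: dict[str, list[tuple[str, int, int]]] = {}
        for protein, doms in intervals.items():
            entries = []
            for name, (start, end) in doms.items():
                if not start < end:
                    raise ValueError(
                        f"{protein}/{name}: interval start must be < end"
                    )
                entries.append((name, int(start), int(end)))
            entries.sort(key=lambda t: t[1])
            for (n1, s1, e1), (n2, s2, e2) in zip(entries, entries[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{protein}: intervals {n1} and {n2} overlap"
                    )
            self._domains[protein] = entries

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainMap":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def kif5b_default(cls) -> "DomainMap":
        ref = importlib.resources.files("kinfold.data") / "kif5b_domains.yaml"
        return cls(yaml.safe_load(ref.read_text()))

    def proteins(self) -> list[str]:
        return list(self._domains)

    def domain_of(self, protein: str, site: int) -> str | None:
        for name, start, end in self._domains.get(protein, ()):
            if start <= site < end:
                return name
        return None

    def interval(self, protein: str, domain: str) -> tuple[int, int]:
        for name, start, end in self._domains[protein]:
            if name == domain:
                return start, end
        raise KeyError(f"{protein} has no domain {domain!r}")


@dataclass(frozen=True)
class AssignedCrosslink:
    """A crosslink resolved to specific chains, with its distance and verdict."""

    record: CrosslinkRecord
    chain_a: str
    chain_b: str
    distance: float
    satisfied: bool
    group: str


@dataclass
class ValidationReport:
    """Aggregate restraint-validation result for one model."""

    assigned: list[AssignedCrosslink]
    threshold: float
    n_total: int = field(init=False)
    n_satisfied: int = field(init=False)
    fraction_satisfied: float = field(init=False)
    group_counts: Counter = field(init=False)
    group_satisfied: Counter = field(init=False)
    group_distance_ranges: dict = field(init=False)
    distance_range: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.assigned:
            raise EmptyReportError("no crosslinks to report on")
        self.n_total = len(self.assigned)
        self.n_satisfied = sum(a.satisfied for a in self.assigned)
        self.fraction_satisfied = self.n_satisfied / self.n_total
        self.group_counts = Counter(a.group for a in self.assigned)
        self.group_satisfied = Counter(
            a.group for a in self.assigned if a.satisfied
        )
        dists = [a.distance for a in self.assigned]
        self.distance_range = (min(dists), max(dists))
        self.group_distance_ranges = {}
        for g in self.group_counts:
            gd = [a.distance for a in self.assigned if a.group == g]
            self.group_distance_ranges[g] = (min(gd), max(gd))

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_total": self.n_total,
            "n_satisfied": self.n_satisfied,
            "fraction_satisfied": self.fraction_satisfied,
            "distance_range": list(self.distance_range),
            "group_counts": dict(self.group_counts),
            "group_satisfied": dict(self.group_satisfied),
            "group_distance_ranges": {
                g: list(r) for g, r in self.group_distance_ranges.items()
            },
            "links": [
                {
                    "protein_a": a.record.protein_a,
                    "site_a": a.record.site_a,
                    "protein_b": a.record.protein_b,
                    "site_b": a.record.site_b,
                    "evalue": a.record.evalue,
                    "chain_a": a.chain_a,
                    "chain_b": a.chain_b,
                    "distance": a.distance,
                    "satisfied": a.satisfied,
                    "group": a.group,
                }
                for a in sorted(self.assigned, key=lambda a: a.record.source_row)
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def group_summary(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.group_counts):
            lo, hi = self.group_distance_ranges[g]
            rows.append(
                {
                    "group": g,
                    "n": self.group_counts[g],
                    "n_satisfied": self.group_satisfied.get(g, 0),
                    "min_distance": lo,
                    "max_distance": hi,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

# per column: accepted header spellings, case-insensitive (pLink-style exports
# use Protein1/Protein2 and site or position columns)
_DEFAULT_COLUMNS = {
    "protein_a": ("protein1", "protein_a", "proteina", "protein 1"),
    "site_a": ("site1", "site_a", "position1", "abspos1"),
    "protein_b": ("protein2", "protein_b", "proteinb", "protein 2"),
    "site_b": ("site2", "site_b", "position2", "abspos2"),
    "evalue": ("evalue", "e-value", "e_value", "e value", "score"),
}


def _resolve_columns(df: pd.DataFrame, columns: Mapping[str, str] | None) -> dict:
    lower = {c.lower().strip(): c for c in df.columns}
    resolved = {}
    for key, aliases in _DEFAULT_COLUMNS.items():
        if columns and key in columns:
            if columns[key] not in df.columns:
                raise SchemaError(f"configured column {columns[key]!r} not in file")
            resolved[key] = columns[key]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[key] = lower[alias]
                break
        else:
            raise SchemaError(
                f"missing required column for {key!r} "
                f"(accepted names: {', '.join(aliases)})"
            )
    return resolved


def parse_crosslinks(
    path: str | Path,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    columns: Mapping[str, str] | None = None,
) -> list[CrosslinkRecord]:
    """Parse a pLink-style crosslink table into deduplicated records.

    Rows with E-value >= ``evalue_threshold`` are dropped (strict less-than
    keeps a row).  Unordered duplicates (P,i)-(Q,j) vs (Q,j)-(P,i) collapse to
    one record keeping the minimum E-value; self-pairs are removed.  The
    delimiter (comma or tab) is sniffed from the header line.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = _resolve_columns(df, columns)
    best: dict[tuple, CrosslinkRecord] = {}
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        data = dict(zip(df.columns, row))
        try:
            evalue = float(data[cols["evalue"]])
            site_a = int(data[cols["site_a"]])
            site_b = int(data[cols["site_b"]])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {row_number}: {exc}") from None
        if not math.isfinite(evalue) or evalue <= 0:
            raise ParseError(f"row {row_number}: non-positive E-value {evalue!r}")
        if evalue >= evalue_threshold:
            continue
        rec = CrosslinkRecord(
            protein_a=str(data[cols["protein_a"]]).strip(),
            site_a=site_a,
            protein_b=str(data[cols["protein_b"]]).strip(),
            site_b=site_b,
            evalue=evalue,
            source_row=row_number,
        )
        if (rec.protein_a, rec.site_a) == (rec.protein_b, rec.site_b):
            continue  # self-pair
        key = rec.unordered_key
        if key not in best or rec.evalue < best[key].evalue:
            best[key] = rec
    return sorted(best.values(), key=lambda r: r.source_row)


# ---------------------------------------------------------------------------
# Classification and chain assignment
# ---------------------------------------------------------------------------

def classify_contact(record: CrosslinkRecord, domains: DomainMap) -> str:
    """Bin a crosslink into one of the folded-motor contact groups."""
    if record.protein_a != record.protein_b:
        return "interprotein"
    da = domains.domain_of(record.protein_a, record.site_a)
    db = domains.domain_of(record.protein_b, record.site_b)
    if da is None or db is None:
        return "other"
    pair = {da, db}
    if pair == {"motor"}:
        return "motor_intra"
    if "motor" in pair:
        other = (pair - {"motor"}).pop()
        if other in _TAIL_LIKE_DOMAINS:
            return "motor_tail"
        if other == "cc2":
            return "motor_cc2"
        return "other"
    if pair <= _STALK_DOMAINS:
        return "stalk_intra"
    if pair <= (_STALK_DOMAINS | {"tail"}):
        return "stalk_intra"
    return "other"


def _chains_with_site(
    model: StructureModel, site: int, anchor: str, chains: Sequence[str]
) -> list[str]:
    return [c for c in chains if model.has_site((c, site, anchor))]


def assign_chains(
    record: CrosslinkRecord,
    model: StructureModel,
    anchor: str = "CA",
    chain_map: Mapping[str, Sequence[str]] | None = None,
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    domains: DomainMap | None = None,
) -> AssignedCrosslink:
    """Resolve homodimer chain ambiguity by shortest anchor-atom distance.

    All valid chain combinations (including intra-chain) are enumerated and
    the minimum-distance assignment returned; ties break lexicographically on
    (chain_a, chain_b).
    """
    all_chains = model.chain_ids()
    chains_a = (
        list(chain_map[record.protein_a])
        if chain_map and record.protein_a in chain_map
        else all_chains
    )
    chains_b = (
        list(chain_map[record.protein_b])
        if chain_map and record.protein_b in chain_map
        else all_chains
    )
    cand_a = _chains_with_site(model, record.site_a, anchor, chains_a)
    cand_b = _chains_with_site(model, record.site_b, anchor, chains_b)
    if not cand_a or not cand_b:
        missing = record.site_a if not cand_a else record.site_b
        raise SiteLookupError(
            f"residue {missing} (anchor {anchor}) absent from chains "
            f"{all_chains}; crosslink row {record.source_row}"
        )
    best: tuple[float, str, str] | None = None
    for ca, cb in itertools.product(sorted(cand_a), sorted(cand_b)):
        if (ca, record.site_a) == (cb, record.site_b):
            continue  # same physical residue
        d = float(
            np.linalg.norm(
                model.position((ca, record.site_a, anchor))
                - model.position((cb, record.site_b, anchor))
            )
        )
        key = (d, ca, cb)
        if best is None or key < best:
            best = key
    if best is None:
        raise SiteLookupError(
            f"crosslink row {record.source_row}: no valid chain combination"
        )
    d, ca, cb = best
    group = classify_contact(record, domains) if domains is not None else "other"
    return AssignedCrosslink(
        record=record,
        chain_a=ca,
        chain_b=cb,
        distance=d,
        satisfied=d <= threshold,
        group=group,
    )


def evaluate_restraints(
    records: Sequence[CrosslinkRecord],
    model: StructureModel,
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    domains: DomainMap | None = None,
    anchor: str = "CA",
    chain_map: Mapping[str, Sequence[str]] | None = None,
) -> ValidationReport:
    """Assign, classify and score every crosslink against the distance limit.

    Satisfaction is inclusive: distance <= threshold counts as within the
    crosslinker span.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not records:
        raise EmptyReportError("cannot validate an empty crosslink list")
    assigned = [
        assign_chains(
            r, model, anchor=anchor, chain_map=chain_map,
            threshold=threshold, domains=domains,
        )
        for r in records
    ]
    return ValidationReport(assigned=assigned, threshold=threshold)


def export_pseudobonds(
    report: ValidationReport, path: str | Path, anchor: str = "CA"
) -> None:
    """Write one pseudobond line per assigned crosslink (ChimeraX-style specs).

    Format: /chain_a:res_a@atom /chain_b:res_b@atom distance satisfied group
    Lines are ordered by the crosslink's source row, so output is stable.
    """
    lines = []
    for a in sorted(report.assigned, key=lambda a: a.record.source_row):
        flag = "satisfied" if a.satisfied else "violated"
        lines.append(
            f"/{a.chain_a}:{a.record.site_a}@{anchor} "
            f"/{a.chain_b}:{a.record.site_b}@{anchor} "
            f"{a.distance:.1f} {flag} {a.group}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
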