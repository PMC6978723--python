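"""Map proteome detections onto pathway reactions and score completeness.

The discriminating observation for the pathway question is qualitative:
which enzymes of each candidate route are present in the proteome of
galacturonate-grown cells. A reaction counts as *detected* when at least
one of its mapped proteins (paralogs allowed) appears in the proteome
table; detection is binary because the input table is already filtered
upstream (peptide-level acceptance criteria are not re-applied here).

Reactions whose evidence is only a *candidate* assignment — the mannonate
kinase and 6-phosphomannonate 2-epimerase, whose structural genes are
unresolved — are reported separately and never counted toward the
completeness fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pathways import PathwayModel, Reaction

__all__ = [
    "ProteomeTable",
    "EvidenceMap",
    "CompletenessReport",
    "pathway_completeness",
    "percentile_rank",
    "load_table3_fixture",
    "load_lcv1_evidence_map",
]


@dataclass
class ProteomeTable:
    """Detected proteins, optionally with normalized spectral counts."""

    detected: set[str] = field(default_factory=set)
    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative spectral count for {pid}")
            if c > 0:
                self.detected.add(pid)

    def __contains__(self, pid: str) -> bool:
        return pid in self.detected

    def __len__(self) -> int:
        return len(self.detected)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, float]]) -> "ProteomeTable":
        counts: dict[str, float] = {}
        for pid, c in rows:
            if pid in counts:
                raise ValueError(f"duplicate protein id {pid!r}")
            counts[pid] = float(c)
        return cls(counts=counts)


@dataclass
class EvidenceMap:
    """Evidence key -> protein ids, split into confirmed and candidate tiers."""

    mapping: dict[str, tuple[str, ...]] = field(default_factory=dict)
    candidate: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def proteins_for(self, key: str) -> tuple[str, ...]:
        if key in self.mapping:
            return self.mapping[key]
        raise KeyError(f"evidence key {key!r} is not in the map")

    @classmethod
    def from_file(cls, path: str | Path) -> "EvidenceMap":
        """Read a map file: ``key [candidate]: id1 id2 ...`` per line."""
        mapping: dict[str, tuple[str, ...]] = {}
        candidate: dict[str, tuple[str, ...]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            head, _, rest = line.partition(":")
            ids = tuple(rest.split())
            head = head.strip()
            if head.endswith("[candidate]"):
                candidate[head[:-len("[candidate]")].strip()] = ids
            else:
                mapping[head] = ids
        return cls(mapping, candidate)


@dataclass(frozen=True)
class CompletenessReport:
    """Per-reaction detection status and the completeness fraction.

    ``completeness`` = detected / (detected + not detected); reactions with
    only candidate-tier evidence are listed in ``candidate_status`` and
    excluded from the fraction.
    """

    pathway: str
    status: dict[str, str]                    # reaction id -> detected|not-detected
    candidate_status: dict[str, str]          # candidate-tier reactions
    completeness: float
    missing: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "pathway": self.pathway,
            "status": dict(self.status),
            "candidate_status": dict(self.candidate_status),
            "completeness": self.completeness,
            "missing": list(self.missing),
        }


def _reaction_detected(r: Reaction, em: EvidenceMap, pt: ProteomeTable) -> bool:
    hit = False
    for key in r.evidence:
        for pid in em.proteins_for(key):
            if pid in pt:
                hit = True
    return hit


def pathway_completeness(
    p: PathwayModel,
    em: EvidenceMap,
    pt: ProteomeTable,
    reactions: Sequence[str] | None = None,
) -> CompletenessReport:
    """Score which reactions of a pathway have proteome support.

    ``reactions`` optionally restricts the scoring to a subset of reaction
    ids (e.g. the upper-pathway core). Raises ``KeyError`` naming the
    reaction when an evidence key is missing from the map.
    """
    chosen = p.reactions if reactions is None else [p.reaction(r) for r in reactions]
    status: dict[str, str] = {}
    cand: dict[str, str] = {}
    missing: list[str] = []
    for r in chosen:
        for key in r.evidence:
            if key not in em.mapping:
                raise KeyError(
                    f"reaction {r.id}: evidence key {key!r} absent from map")
        if not r.evidence:
            if r.candidate_evidence:
                hit = any(pid in pt
                          for key in r.candidate_evidence
                          for pid in em.candidate.get(key, ()))
                cand[r.id] = "candidate-detected" if hit else "candidate-not-detected"
            else:
                cand[r.id] = "unmapped"
            continue
        if _reaction_detected(r, em, pt):
            status[r.id] = "detected"
        else:
            status[r.id] = "not-detected"
            missing.append(r.id)
    n = len(status)
    frac = (sum(1 for s in status.values() if s == "detected") / n) if n else 0.0
    return CompletenessReport(p.name, status, cand, frac, tuple(missing))


def percentile_rank(pt: ProteomeTable, subset: Sequence[str]) -> dict[str, float]:
    """Percentile of each queried protein's count in the full distribution.

    Percentile = 100 x (strictly below + (ties - 1)/2) / n — the
    "strictly below, mean tie handling" convention, which is invariant to
    any strictly monotone transformation of the counts.
    """
    if not pt.counts:
        raise ValueError("proteome table carries no spectral counts")
    counts = np.array(list(pt.counts.values()))
    n = len(counts)
    out = {}
    for pid in subset:
        if pid not in pt.counts:
            raise KeyError(f"protein {pid!r} has no count in the table")
        c = pt.counts[pid]
        below = int(np.sum(counts < c))
        ties = int(np.sum(counts == c))
        out[pid] = 100.0 * (below + (ties - 1) / 2.0) / n
    return out


def load_table3_fixture() -> ProteomeTable:
    """The packaged detection-only proteome fixture (transcribed gene table)."""
    path = resources.files("galuferm.data.fixtures").joinpath("lcv1_proteome.tsv")
    detected = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line == "protein_id":
            continue
        detected.add(line.split("\t")[0])
    return ProteomeTable(detected=detected)


def load_lcv1_evidence_map() -> EvidenceMap:
    """The packaged gene-to-protein evidence map for strain LCV1."""
    path = resources.files("galuferm.data.fixtures").joinpath("lcv1_evidence.map")
    with resources.as_file(path) as p:
        return EvidenceMap.from_file(p)
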