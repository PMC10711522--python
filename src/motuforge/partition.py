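"""The Partition container shared by every delimitation method."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from sklearn.metrics import adjusted_rand_score

from .errors import ValidationError

METHODS = {"SLC", "ASAP", "PTP", "mPTP", "GMYC", "mGMYC", "MORPHOLOGY", "CONSENSUS"}


@dataclass
class Partition:
    """A total assignment of sequence ids to MOTU labels.

    ``method`` records which algorithm produced it; any string is accepted
    so user-defined schemes can take part in a consensus.
    """

    method: str
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValidationError("empty partition")
        for sid, label in self.assignment.items():
            if label is None or label == "":
                raise ValidationError(f"sequence {sid!r} has no MOTU label")

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, label in self.assignment.items():
            out.setdefault(label, []).append(sid)
        return out

    def relabel(self, prefix: str = "MOTU") -> "Partition":
        """Canonical labels MOTU0001.. in order of first appearance."""
        mapping: dict[str, str] = {}
        new = {}
        for sid in self.assignment:
            old = self.assignment[sid]
            if old not in mapping:
                mapping[old] = f"{prefix}{len(mapping) + 1:04d}"
            new[sid] = mapping[old]
        return Partition(self.method, new)

    def expand(self, multiplicity: Mapping[str, Iterable[str]]) -> "Partition":
        """Re-expand a haplotype-level partition to all member sequences.

        ``multiplicity`` maps each representative id to the full list of
        member ids it stands for (itself included).
        """
        new = {}
        for rep, label in self.assignment.items():
            for member in multiplicity.get(rep, [rep]):
                new[member] = label
        return Partition(self.method, new)

    def ari(self, other: "Partition") -> float:
        """Adjusted Rand index against another partition over the same ids."""
        if self.ids != other.ids:
            raise ValidationError("partitions cover different id sets")
        ids = sorted(self.ids)
        return float(
            adjusted_rand_score(
                [self.assignment[i] for i in ids], [other.assignment[i] for i in ids]
            )
        )


def partition_from_labels(method: str, labels: Mapping[str, str]) -> Partition:
    return Partition(method=method, assignment=dict(labels))
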