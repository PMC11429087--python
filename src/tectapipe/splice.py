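"""Amplicon-length prediction for splice-blocking morpholino knockdowns.

A splice-site-blocking morpholino produces aberrant transcripts — skipped
internal exons or retained cryptic-splice segments.  Given the per-exon
contributions (bp) to a primer-bounded RT-PCR amplicon, this module
predicts the band sizes those variants produce on a gel.  Lengths only:
no sequences, primers or alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import InputError

__all__ = [
    "GeneModelFixture",
    "SpliceVariant",
    "amplicon_length",
    "variant_catalog",
    "DHPS_AMPLICON",
]


@dataclass(frozen=True)
class GeneModelFixture:
    """Ordered exon contributions (bp) to the primer-bounded amplicon.

    The first and last exons carry the primer anchors and can never be
    skipped.  Only the totals are meaningful: when a reference amplicon is
    known only as (full length, length after skipping exon k), the split of
    the remaining length between the terminal exons is a fixture convention.
    """

    exon_contributions: tuple[int, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.exon_contributions) < 2:
            raise InputError("need at least two exons (primer anchors)")
        if any(length <= 0 for length in self.exon_contributions):
            raise InputError("exon contributions must be positive")
        if self.labels and len(self.labels) != len(self.exon_contributions):
            raise InputError("labels must match exon count")

    @property
    def n_exons(self) -> int:
        return len(self.exon_contributions)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneModelFixture":
        data = json.loads(Path(path).read_text())
        return cls(
            exon_contributions=tuple(data["exon_contributions"]),
            labels=tuple(data.get("labels", ())),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "exon_contributions": list(self.exon_contributions),
                    "labels": list(self.labels),
                },
                indent=2,
            )
        )


@dataclass(frozen=True)
class SpliceVariant:
    """An aberrant transcript: skipped internal exons and/or a retained
    cryptic segment of ``inserted_bp`` bases."""

    skipped_exons: frozenset[int] = field(default_factory=frozenset)
    inserted_bp: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "skipped_exons", frozenset(self.skipped_exons))
        if self.inserted_bp < 0:
            raise InputError("inserted_bp must be non-negative")


def amplicon_length(gene: GeneModelFixture, variant: SpliceVariant) -> int:
    """Predicted amplicon length: non-skipped exon contributions + insertion."""
    terminal = {0, gene.n_exons - 1}
    for k in variant.skipped_exons:
        if not 0 <= k < gene.n_exons:
            raise InputError(f"exon index {k} out of range")
        if k in terminal:
            raise InputError("cannot skip a primer-bearing terminal exon")
    kept = sum(
        length
        for i, length in enumerate(gene.exon_contributions)
        if i not in variant.skipped_exons
    )
    return kept + variant.inserted_bp


def variant_catalog(
    gene: GeneModelFixture, insertions: Sequence[int] = ()
) -> list[tuple[SpliceVariant, int]]:
    """Enumerate the canonical transcript, every single internal-exon skip,
    and the requested cryptic-insertion variants, with predicted lengths."""
    variants = [SpliceVariant(name="canonical")]
    for k in range(1, gene.n_exons - 1):
        variants.append(SpliceVariant(skipped_exons={k}, name=f"skip_exon{k + 1}"))
    for ins in insertions:
        variants.append(
            SpliceVariant(inserted_bp=ins, name=f"insert_{ins}bp")
        )
    return [(v, amplicon_length(gene, v)) for v in variants]


# Reference fixture for the zebrafish dhps exon-1..3 RT-PCR amplicon: the
# full amplicon is 375 bp and skipping exon 2 leaves 172 bp, so exon 2
# contributes 203 bp; the 100/72 split between the terminal exons is a
# convention (only their 172 bp sum is constrained).
DHPS_AMPLICON = GeneModelFixture(
    exon_contributions=(100, 203, 72),
    labels=("exon1", "exon2", "exon3"),
)
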