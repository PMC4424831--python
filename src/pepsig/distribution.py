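"""Positional profiles of conserved peptides along protein sequences.

Each conserved hexapeptide is assigned a single position: the median,
over all member proteins containing it, of its first-occurrence start
(1-based).  The median rather than the mean makes the position robust
to length variation and truncated sequences.  Binning the medians into
20-residue intervals gives a per-subfamily profile of where the
conserved region lies, and summing profiles across subfamilies gives
the accumulated family-level profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ppr import PeptideGroup
from .seqio import ProteinRecord


@dataclass
class PositionProfile:
    """Binned counts of conserved-peptide median positions.

    ``counts`` maps the 1-based bin start (1, 21, 41, ... for the
    default 20-residue bins) to the number of peptides whose median
    position falls in that bin.
    """

    group_id: str
    bin_width: int = 20
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        starts = sorted(self.counts)
        return pd.DataFrame({
            "group_id": self.group_id,
            "bin_start": starts,
            "bin_end": [s + self.bin_width - 1 for s in starts],
            "count": [self.counts[s] for s in starts],
        })


def peptide_position(peptide: str, proteins: Sequence[ProteinRecord]) -> int:
    """Median 1-based first-occurrence start over containing proteins.

    Proteins not containing the peptide are ignored; for an even number
    of containing proteins the lower median is returned.
    """
    positions = []
    for p in proteins:
        idx = p.seq.find(peptide)
        if idx >= 0:
            positions.append(idx + 1)
    if not positions:
        raise ValueError(f"peptide {peptide!r} absent from all proteins")
    positions.sort()
    return positions[(len(positions) - 1) // 2]


def position_profile(group: PeptideGroup, members: Sequence[ProteinRecord],
                     bin_width: int = 20) -> PositionProfile:
    """Bin the median positions of a subfamily's peptides.

    Each peptide with at least one occurrence among the member proteins
    contributes one count to the bin containing its median position;
    bins are [1, bin_width], [bin_width+1, 2*bin_width], ...
    """
    counts: dict[int, int] = {}
    for pep in sorted(group.peptides):
        try:
            pos = peptide_position(pep, members)
        except ValueError:
            continue
        bin_start = ((pos - 1) // bin_width) * bin_width + 1
        counts[bin_start] = counts.get(bin_start, 0) + 1
    return PositionProfile(group_id=group.id, bin_width=bin_width, counts=counts)


def accumulated_profile(profiles: Sequence[PositionProfile],
                        group_id: str = "accumulated") -> PositionProfile:
    """Bin-wise sum of profiles (all must share one bin width)."""
    if not profiles:
        return PositionProfile(group_id=group_id)
    widths = {p.bin_width for p in profiles}
    if len(widths) > 1:
        raise ValueError(f"mismatched bin widths: {sorted(widths)}")
    counts: dict[int, int] = {}
    for p in profiles:
        for start, c in p.counts.items():
            counts[start] = counts.get(start, 0) + c
    return PositionProfile(group_id=group_id, bin_width=widths.pop(), counts=counts)


def write_profiles(profiles: Iterable[PositionProfile], path: str | Path) -> None:
    """Write profiles to TSV: group_id, bin_start, bin_end, count."""
    frames = [p.to_frame() for p in profiles]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["group_id", "bin_start", "bin_end", "count"]))
    out.to_csv(path, sep="\t", index=False)
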