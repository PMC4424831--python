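"""Genome annotation by peptide-pattern matching in translated frames.

A genome is mined for genes by looking for a subfamily's conserved
hexapeptides in six-frame translations — conceptually an in-silico PCR
with highly degenerate primers.  Two modes:

* fungal — the genome is split into 2000-base fragments with 100-base
  overlap (genes may straddle exon/intron structure, so no ORF model is
  imposed); every fragment is scored in all six frames against every
  subfamily list, and significant same-family hits closer than 5800
  bases (start-to-start) are chained into one gene call.
* bacterial — the whole genome is translated in six frames, stop-free
  open reading frames longer than 50 amino acids are scored, and each
  significant ORF is reported as an independent call (no merging).

A hit is significant only if all three conditions hold: at least three
distinct list peptides present, frequency score strictly greater than
1.0, and at least ten residues covered by the matched peptides (three
maximally overlapping hexapeptides cover only 8 residues and are
rejected; three non-overlapping ones cover 18).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .ppr import PeptideGroup, enumerate_peptides
from .seqio import (
    GenomeFragment,
    GenomeRecord,
    extract_orfs,
    fragment_genome,
    six_frame_translate,
)


@dataclass
class HotpepConfig:
    """Significance thresholds, merge distance and annotation mode."""

    min_peptides: int = 3
    min_score: float = 1.0
    min_covered_aa: int = 10
    merge_distance: int = 5800
    window: int = 2000
    overlap: int = 100
    min_orf_len: int = 50
    mode: Literal["fungal", "bacterial"] = "fungal"

    def __post_init__(self) -> None:
        for name in ("min_peptides", "min_score", "min_covered_aa",
                     "merge_distance", "window", "min_orf_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("fungal", "bacterial"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class FrameHit:
    """A scored match of one peptide list against one translated frame."""

    genome_id: str
    fragment_start: int
    fragment_end: int
    frame: int
    group_id: str
    family: str
    n_peptides: int
    frequency_score: float
    covered_aa: int


@dataclass(frozen=True)
class GeneCall:
    """A merged genome-coordinate annotation (0-based half-open interval)."""

    genome_id: str
    family: str
    group_id: str
    start: int
    end: int
    score: float
    n_fragments: int


def is_significant_stats(n_peptides: int, frequency_score: float, covered_aa: int,
                         config: HotpepConfig | None = None) -> bool:
    """Conjunction of the three significance conditions.

    Peptide count and coverage are inclusive bounds; the score bound is
    strict (a single perfectly conserved peptide scores exactly 1.0 and
    fails).
    """
    config = config or HotpepConfig()
    return (n_peptides >= config.min_peptides
            and frequency_score > config.min_score
            and covered_aa >= config.min_covered_aa)


def is_significant(hit: FrameHit, config: HotpepConfig | None = None) -> bool:
    """Whether a frame hit passes all three significance conditions."""
    return is_significant_stats(hit.n_peptides, hit.frequency_score,
                                hit.covered_aa, config)


class PeptideIndex:
    """Inverted index peptide -> [(group index, frequency)] over many groups.

    Lets a translated frame be scored against every subfamily list in a
    single pass over its k-mers.
    """

    def __init__(self, groups: Sequence[PeptideGroup], k: int = 6):
        self.groups = list(groups)
        self.k = k
        self._index: dict[str, list[tuple[int, float]]] = {}
        for gi, g in enumerate(self.groups):
            for pep, freq in g.peptides.items():
                if len(pep) != k:
                    raise ValueError(
                        f"group {g.id}: peptide {pep!r} is not a {k}-mer")
                self._index.setdefault(pep, []).append((gi, freq))

    def score_all(self, aa_seq: str) -> list[tuple[int, float, int]]:
        """(n_peptides, frequency_score, covered_aa) per group for one frame."""
        occurrences = enumerate_peptides(aa_seq, self.k)
        n = [0] * len(self.groups)
        score = [0.0] * len(self.groups)
        covered: dict[int, set[int]] = {}
        for pep, starts in occurrences.items():
            for gi, freq in self._index.get(pep, ()):
                n[gi] += 1
                score[gi] += freq
                residues = covered.setdefault(gi, set())
                for s in starts:
                    residues.update(range(s, s + self.k))
        return [(n[gi], score[gi], len(covered.get(gi, ())))
                for gi in range(len(self.groups))]


def score_frame(aa_seq: str, group: PeptideGroup, k: int = 6) -> tuple[int, float, int]:
    """Score one peptide list against one translated frame.

    Same contract as scoring a protein; '*' and 'X' never participate
    in a match because peptide lists contain only canonical residues.
    """
    from .ppr import score_sequence

    return score_sequence(aa_seq, group.peptides, k)


def assign_fragment(fragment: GenomeFragment, index: PeptideIndex,
                    config: HotpepConfig | None = None) -> FrameHit | None:
    """Best significant (frame x subfamily) hit for one fragment, or None.

    The fragment contributes at most one hit: the argmax by frequency
    score over all significant frame/group combinations, ties broken by
    peptide count then group id.
    """
    config = config or HotpepConfig()
    best: tuple[float, int, str] | None = None
    best_hit: FrameHit | None = None
    for fr in six_frame_translate(fragment.seq, fragment.genome_id):
        for gi, (n, score, covered) in enumerate(index.score_all(fr.aa_seq)):
            if not is_significant_stats(n, score, covered, config):
                continue
            g = index.groups[gi]
            key = (-score, -n, g.id)
            if best is None or key < best:
                best = key
                best_hit = FrameHit(fragment.genome_id, fragment.start,
                                    fragment.end, fr.frame, g.id, g.family,
                                    n, score, covered)
    return best_hit


def merge_hits(hits: Sequence[FrameHit], config: HotpepConfig | None = None
               ) -> list[GeneCall]:
    """Chain same-family hits closer than the merge distance into gene calls.

    Single-linkage on fragment start positions, per family: consecutive
    hits whose starts differ by strictly less than ``merge_distance``
    belong to one gene.  The call's subfamily and score come from the
    highest-scoring contributing hit; the interval spans all
    contributing fragments.  Different families never merge; strand is
    ignored.
    """
    config = config or HotpepConfig()
    by_family: dict[str, list[FrameHit]] = {}
    for h in hits:
        by_family.setdefault(h.family, []).append(h)
    calls = []
    for family in sorted(by_family):
        chain: list[FrameHit] = []
        for h in sorted(by_family[family], key=lambda h: h.fragment_start):
            if chain and h.fragment_start - chain[-1].fragment_start >= config.merge_distance:
                calls.append(_emit_call(chain))
                chain = []
            chain.append(h)
        if chain:
            calls.append(_emit_call(chain))
    calls.sort(key=lambda c: (c.start, c.family))
    return calls


def _emit_call(chain: Sequence[FrameHit]) -> GeneCall:
    best = min(chain, key=lambda h: (-h.frequency_score, -h.n_peptides, h.group_id))
    return GeneCall(
        genome_id=chain[0].genome_id,
        family=best.family,
        group_id=best.group_id,
        start=min(h.fragment_start for h in chain),
        end=max(h.fragment_end for h in chain),
        score=best.frequency_score,
        n_fragments=len(chain),
    )


def annotate_genome(genome: GenomeRecord, groups: Sequence[PeptideGroup],
                    config: HotpepConfig | None = None) -> list[GeneCall]:
    """Annotate one genome against a set of subfamily peptide lists."""
    config = config or HotpepConfig()
    if len(genome.seq) < 3:
        raise ValueError(f"genome {genome.id!r} shorter than one codon")
    index = PeptideIndex(groups)
    if config.mode == "fungal":
        hits = []
        for frag in fragment_genome(genome, config.window, config.overlap):
            hit = assign_fragment(frag, index, config)
            if hit is not None:
                hits.append(hit)
        return merge_hits(hits, config)

    # bacterial: independent significant ORFs, no merging
    frames = six_frame_translate(genome.seq, genome.id)
    calls = []
    for orf in extract_orfs(frames, config.min_orf_len):
        best: tuple[float, int, str] | None = None
        best_call: GeneCall | None = None
        for gi, (n, score, covered) in enumerate(index.score_all(orf.aa_seq)):
            if not is_significant_stats(n, score, covered, config):
                continue
            g = index.groups[gi]
            key = (-score, -n, g.id)
            if best is None or key < best:
                best = key
                best_call = GeneCall(genome.id, g.family, g.id,
                                     orf.nt_start, orf.nt_end, score, 1)
        if best_call is not None:
            calls.append(best_call)
    calls.sort(key=lambda c: (c.start, c.family))
    return calls


def write_gene_calls(calls: Iterable[GeneCall], path: str | Path) -> None:
    """Write gene calls to TSV (coordinates 1-based inclusive on output)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tfamily\tgroup_id\tstart\tend\tscore\tn_fragments\n")
        for c in calls:
            fh.write(f"{c.genome_id}\t{c.family}\t{c.group_id}\t"
                     f"{c.start + 1}\t{c.end}\t{c.score:.6f}\t{c.n_fragments}\n")


def write_gff3(calls: Iterable[GeneCall], path: str | Path) -> None:
    """Write gene calls as GFF3 (source 'hotpep', type 'gene')."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, 1):
            attrs = (f"ID=gene{i};family={c.family};subfamily={c.group_id};"
                     f"n_fragments={c.n_fragments}")
            fh.write(f"{c.genome_id}\thotpep\tgene\t{c.start + 1}\t{c.end}\t"
                     f"{c.score:.6f}\t.\t.\t{attrs}\n")
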