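"""Synthetic protein families and genomes with planted ground truth.

The generator emulates the statistical structure the peptide-pattern
method assumes: a family is a set of subfamilies, each defined by a
conserved region whose overlapping hexapeptides are that subfamily's
motif set; member proteins embed the region at a subfamily-consistent
offset inside otherwise random sequence.  Genomes are built by
reverse-translating proteins with uniform synonymous codons, framing
each gene with stop codons, placing it on a random strand and
separating genes with random intergenic sequence.

A conserved region of length ``motifs_per_subfamily + 5`` yields
exactly ``motifs_per_subfamily`` overlapping hexamers, mirroring how
conserved peptides in real families tile a conserved region rather
than being scattered.  Motif sets are drawn disjointly across
subfamilies (regenerating on collision), so zero cross-subfamily
sharing is exact by construction, not probabilistic.  Everything is
deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import CANONICAL_AA, GenomeRecord, ProteinRecord

_AA = np.frombuffer(CANONICAL_AA.encode(), dtype="S1")


def _inverse_codon_table() -> dict[str, list[str]]:
    from .seqio import _CODON_TABLE

    inv: dict[str, list[str]] = {}
    for codon, aa in sorted(_CODON_TABLE.items()):
        if aa != "*":
            inv.setdefault(aa, []).append(codon)
    return inv


_CODONS_OF = _inverse_codon_table()
_REVCOMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic family pool."""

    n_families: int = 3
    subfamilies_per_family: int = 4
    proteins_per_subfamily: int = 20
    motifs_per_subfamily: int = 70
    protein_len: tuple[int, int] = (200, 350)
    mutation_rate: float = 0.0
    cross_family_sharing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "subfamilies_per_family",
                     "proteins_per_subfamily", "motifs_per_subfamily"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.cross_family_sharing < 1.0:
            raise ValueError("cross_family_sharing must be in [0, 1)")
        lo, hi = self.protein_len
        region = self.motifs_per_subfamily + 5
        if lo < region:
            raise ValueError(
                f"minimum protein length {lo} cannot hold a conserved region "
                f"of {region} residues")
        if lo > hi:
            raise ValueError("protein_len must be (min, max) with min <= max")


@dataclass(frozen=True)
class PlantedGene:
    """Forward-strand coordinates (0-based half-open) of one planted gene."""

    genome_id: str
    start: int
    end: int
    strand: str
    protein_id: str
    family: str
    subfamily: str


@dataclass
class PlantedTruth:
    """Exhaustive machine-checkable record of everything planted."""

    protein_truth: dict[str, tuple[str, str]] = field(default_factory=dict)
    motifs: dict[str, frozenset[str]] = field(default_factory=dict)
    region_offset: dict[str, int] = field(default_factory=dict)
    genes: list[PlantedGene] = field(default_factory=list)

    @property
    def families(self) -> list[str]:
        return sorted({fam for fam, _ in self.protein_truth.values()})

    def family_labels(self) -> dict[str, str]:
        return {pid: fam for pid, (fam, _) in self.protein_truth.items()}

    def subfamily_labels(self) -> dict[str, str]:
        return {pid: sub for pid, (_, sub) in self.protein_truth.items()}


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_AA, size=n).tobytes().decode()


def _distinct_region(rng: np.random.Generator, n_motifs: int,
                     used: set[str]) -> tuple[str, list[str]]:
    """A random region whose hexamers are distinct and unused elsewhere."""
    for _ in range(1000):
        region = _random_aa(rng, n_motifs + 5)
        motifs = [region[i : i + 6] for i in range(n_motifs)]
        if len(set(motifs)) == n_motifs and used.isdisjoint(motifs):
            used.update(motifs)
            return region, motifs
    raise RuntimeError("could not draw a disjoint conserved region")  # pragma: no cover


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    if mask.any():
        # replace with a uniformly random *different* residue
        current = np.searchsorted(_AA, arr[mask])
        shift = rng.integers(1, len(_AA), size=int(mask.sum()))
        arr[mask] = _AA[(current + shift) % len(_AA)]
    return arr.tobytes().decode()


def generate_family_pool(spec: SyntheticSpec) -> tuple[list[ProteinRecord], PlantedTruth]:
    """Generate labelled proteins for every family and subfamily.

    Each subfamily gets a conserved region planted at a fixed offset in
    all its members; per-residue mutations are applied i.i.d. over the
    whole sequence afterwards.  With ``cross_family_sharing`` > 0 a
    fraction of every subfamily's motifs comes from one conserved
    region shared by all subfamilies of all families.
    """
    rng = np.random.default_rng(spec.seed)
    truth = PlantedTruth()
    used: set[str] = set()
    n_shared = round(spec.cross_family_sharing * spec.motifs_per_subfamily)
    shared_region, shared_motifs = ("", [])
    if n_shared:
        shared_region, shared_motifs = _distinct_region(rng, n_shared, used)

    proteins: list[ProteinRecord] = []
    lo, hi = spec.protein_len
    for fi in range(spec.n_families):
        family = f"FAM{fi + 1}"
        for si in range(spec.subfamilies_per_family):
            subfam = f"{family}_{si + 1:02d}"
            n_own = spec.motifs_per_subfamily - n_shared
            region, motifs = _distinct_region(rng, n_own, used)
            planted = shared_region + region
            if len(planted) > lo:
                raise ValueError(
                    f"minimum protein length {lo} cannot hold the planted "
                    f"region of {len(planted)} residues")
            offset = int(rng.integers(0, lo - len(planted) + 1))
            truth.motifs[subfam] = frozenset(motifs + shared_motifs)
            truth.region_offset[subfam] = offset
            for pi in range(spec.proteins_per_subfamily):
                length = int(rng.integers(lo, hi + 1))
                flank = _random_aa(rng, length - len(planted))
                seq = flank[:offset] + planted + flank[offset:]
                seq = _mutate(rng, seq, spec.mutation_rate)
                pid = f"{subfam}_p{pi + 1:03d}"
                proteins.append(ProteinRecord(id=pid, seq=seq))
                truth.protein_truth[pid] = (family, subfam)
    return proteins, truth


def reverse_translate(protein: ProteinRecord, rng: np.random.Generator) -> str:
    """Nucleotide coding sequence with uniformly random synonymous codons."""
    return "".join(rng.choice(_CODONS_OF[aa]) for aa in protein.seq)


def random_genome(length: int, seed: int, genome_id: str = "random_genome"
                  ) -> GenomeRecord:
    """A uniform-random nucleotide sequence with no planted genes."""
    rng = np.random.default_rng(seed)
    nt = np.frombuffer(b"ACGT", dtype="S1")
    return GenomeRecord(id=genome_id, seq=rng.choice(nt, size=length).tobytes().decode())


def generate_genome(
    proteins: list[ProteinRecord],
    truth: PlantedTruth,
    spacing: tuple[int, int] = (8000, 12000),
    seed: int = 0,
    genome_id: str = "synthetic_genome",
) -> tuple[GenomeRecord, PlantedTruth]:
    """Plant reverse-translated genes in a random genome.

    Each gene is the protein's coding sequence framed by TAA stop
    codons, placed on a uniformly random strand; genes appear in the
    given protein order, separated by random intergenic stretches drawn
    uniformly from ``spacing``.  Gene coordinates (coding region,
    forward strand) are appended to a copy of ``truth``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spacing
    if not 0 <= lo <= hi:
        raise ValueError("spacing must be (min, max) with 0 <= min <= max")
    nt = np.frombuffer(b"ACGT", dtype="S1")

    def intergenic() -> str:
        n = int(rng.integers(lo, hi + 1))
        return rng.choice(nt, size=n).tobytes().decode() if n else ""

    out = PlantedTruth(protein_truth=dict(truth.protein_truth),
                       motifs=dict(truth.motifs),
                       region_offset=dict(truth.region_offset),
                       genes=list(truth.genes))
    parts: list[str] = [intergenic()]
    pos = len(parts[0])
    for protein in proteins:
        cds = reverse_translate(protein, rng)
        construct = "TAA" + cds + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            construct = construct[::-1].translate(_REVCOMP)
        # the coding region sits at [pos+3, pos+3+len(cds)) on either strand
        fam, sub = truth.protein_truth.get(protein.id, ("?", "?"))
        out.genes.append(PlantedGene(genome_id, pos + 3, pos + 3 + len(cds),
                                     strand, protein.id, fam, sub))
        parts.append(construct)
        pos += len(construct)
        gap = intergenic()
        parts.append(gap)
        pos += len(gap)
    return GenomeRecord(id=genome_id, seq="".join(parts)), out


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Write protein labels and gene coordinates to a truth TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record_type\tid\tfamily\tsubfamily\tgenome_id\tstart\tend\tstrand\n")
        for pid in sorted(truth.protein_truth):
            fam, sub = truth.protein_truth[pid]
            fh.write(f"protein\t{pid}\t{fam}\t{sub}\t.\t.\t.\t.\n")
        for g in truth.genes:
            fh.write(f"gene\t{g.protein_id}\t{g.family}\t{g.subfamily}\t"
                     f"{g.genome_id}\t{g.start + 1}\t{g.end}\t{g.strand}\n")
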