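"""Synthetic droplet experiments from KIR genotype configurations.

The generator walks the same path a wet-lab experiment does: a diploid
genotype is assembled from centromeric and telomeric haplotype motifs with
positioned gene loci; many genome copies are fragmented by random breakage
(and optionally cut by a restriction enzyme between two loci); the
resulting molecules — partner-gene singles, KIR2DL5 singles and still-
linked pairs — are confined at random into nanoliter droplets; and the well
is read out as quadrant counts. Every analysis operation in the toolkit can
then be exercised by parameter recovery against known ground truth.

Fragmentation is modeled as a Poisson random-breakage process: a pair of
loci d kb apart survives on one fragment with probability
exp(-d / mean_fragment_kb), times (1 - p_cut) for every restriction site
between them. The default mean fragment length of 50 kb reflects a typical
column-based genomic DNA preparation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import FamilyGenotypes
from .quant import QuadrantCounts

DEFAULT_MEAN_FRAGMENT_KB = 50.0
#: Gap between the centromeric and telomeric motifs of one haplotype (kb);
#: only long-range (cross-motif) linkage experiments are sensitive to it.
DEFAULT_INTER_MOTIF_GAP_KB = 40.0

GENE_2DL5 = "KIR2DL5"
GENE_2DL2 = "KIR2DL2"
GENE_3DS1 = "KIR3DS1"
GENE_2DS3 = "KIR2DS3"
GENE_2DS5 = "KIR2DS5"
GENE_RPP30 = "RPP30"


@dataclass(frozen=True)
class HaplotypeMotif:
    """A centromeric or telomeric gene arrangement.

    Only the loci the toolkit assays are positioned; positions are kb from
    the motif start. ``length_kb`` sets where the next motif begins."""

    name: str
    genes: tuple  # ((gene_name, position_kb), ...) strictly increasing
    length_kb: float = 70.0

    def __post_init__(self) -> None:
        pos = [p for _, p in self.genes]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"motif {self.name}: positions must be strictly increasing")
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            raise ValueError(f"motif {self.name}: duplicate gene names")


def default_motif_library() -> dict:
    """The five canonical motifs with the assayed loci positioned.

    cB01 carries the KIR2DL2~KIR2DL5 pair 21.8 kb apart (with KIR2DS3
    downstream); tB01 carries KIR3DS1~KIR2DL5 19.9 kb apart (with KIR2DS5
    downstream); cB02 has KIR2DL2 but no centromeric KIR2DL5; cA01 and tA01
    carry none of the assayed loci.
    """
    return {
        "cA01": HaplotypeMotif("cA01", ()),
        "cB01": HaplotypeMotif(
            "cB01", ((GENE_2DL2, 10.0), (GENE_2DL5, 31.8), (GENE_2DS3, 40.0))
        ),
        "cB02": HaplotypeMotif("cB02", ((GENE_2DL2, 10.0),)),
        "tA01": HaplotypeMotif("tA01", ()),
        "tB01": HaplotypeMotif(
            "tB01", ((GENE_3DS1, 5.0), (GENE_2DL5, 24.9), (GENE_2DS5, 33.0))
        ),
    }


@dataclass(frozen=True)
class Haplotype:
    """One chromosome's worth of positioned assay loci."""

    name: str  # e.g. "cB01~tA01"
    loci: tuple  # ((gene_name, absolute_position_kb), ...)

    def positions_of(self, gene: str):
        return [p for g, p in self.loci if g == gene]

    def count(self, gene: str) -> int:
        return sum(1 for g, _ in self.loci if g == gene)


@dataclass(frozen=True)
class Genotype:
    haplotype1: Haplotype
    haplotype2: Haplotype

    @property
    def haplotypes(self):
        return (self.haplotype1, self.haplotype2)

    def count(self, gene: str) -> int:
        return self.haplotype1.count(gene) + self.haplotype2.count(gene)

    def carries(self, gene: str) -> bool:
        return self.count(gene) > 0


@dataclass(frozen=True)
class FragmentationModel:
    """Random breakage plus optional site-specific restriction cuts.

    ``mean_fragment_kb`` may be ``inf`` for intact DNA. Cut sites are
    (absolute position kb, cut probability) pairs on haplotype coordinates.
    """

    mean_fragment_kb: float = DEFAULT_MEAN_FRAGMENT_KB
    cut_sites: tuple = ()

    def __post_init__(self) -> None:
        if not self.mean_fragment_kb > 0:
            raise ValueError("mean fragment length must be positive")
        if any(not 0 <= p <= 1 for _, p in self.cut_sites):
            raise ValueError("cut probabilities must lie in [0, 1]")

    def pair_intact_probability(self, pos1: float, pos2: float) -> float:
        """Probability that two loci remain on one molecule."""
        lo, hi = sorted((pos1, pos2))
        p = float(np.exp(-(hi - lo) / self.mean_fragment_kb))
        for site, p_cut in self.cut_sites:
            if lo < site < hi:
                p *= 1.0 - p_cut
        return p


INTACT_DNA = FragmentationModel(mean_fragment_kb=np.inf)


@dataclass(frozen=True)
class DuplexAssay:
    """Two targets probed on the two fluorescence channels."""

    target_a: str
    target_b: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.target_a == self.target_b:
            raise ValueError("duplex targets must be distinct")
        if not self.name:
            object.__setattr__(self, "name", f"{self.target_a}~{self.target_b}")


ASSAY_2DL2_2DL5 = DuplexAssay(GENE_2DL2, GENE_2DL5)
ASSAY_3DS1_2DL5 = DuplexAssay(GENE_3DS1, GENE_2DL5)


@dataclass(frozen=True)
class SpeciesCounts:
    """Molecule species feeding one duplex well."""

    a_only: int
    b_only: int
    linked_ab: int


def build_haplotype(motif_pair: str, library: dict,
                    gap_kb: float = DEFAULT_INTER_MOTIF_GAP_KB) -> Haplotype:
    """Assemble one haplotype from a 'cen~tel' motif-pair name."""
    parts = motif_pair.replace(" ", "").split("~")
    if len(parts) != 2:
        raise ValueError(f"haplotype name {motif_pair!r} must be 'cen~tel'")
    cen_name, tel_name = parts
    for nm in parts:
        if nm not in library:
            raise KeyError(f"unknown motif {nm!r}; library has {sorted(library)}")
    cen, tel = library[cen_name], library[tel_name]
    loci = [(g, p) for g, p in cen.genes]
    offset = cen.length_kb + gap_kb
    loci += [(g, offset + p) for g, p in tel.genes]
    return Haplotype(name=f"{cen_name}~{tel_name}", loci=tuple(loci))


def build_genotype(motif_pair_h1: str, motif_pair_h2: str,
                   motif_library: dict | None = None,
                   gap_kb: float = DEFAULT_INTER_MOTIF_GAP_KB) -> Genotype:
    """Diploid genotype from two 'cen~tel' motif-pair names."""
    lib = motif_library if motif_library is not None else default_motif_library()
    g = Genotype(
        haplotype1=build_haplotype(motif_pair_h1, lib, gap_kb),
        haplotype2=build_haplotype(motif_pair_h2, lib, gap_kb),
    )
    for h in g.haplotypes:
        if h.count(GENE_2DL5) > 2:
            raise ValueError(f"haplotype {h.name} carries >2 KIR2DL5 copies")
    return g


def _pair_loci(haplotype: Haplotype, assay: DuplexAssay):
    """Greedy nearest-neighbour pairing of A and B target loci.

    Each locus belongs to at most one pair; closest pairs are formed first,
    so the canonical adjacent arrangements pair up before any long-range
    combination. Returns (pairs, lone_a, lone_b) as position lists."""
    a_pos = haplotype.positions_of(assay.target_a)
    b_pos = haplotype.positions_of(assay.target_b)
    candidates = sorted(
        ((abs(pa - pb), pa, pb) for pa in a_pos for pb in b_pos),
        key=lambda t: t[0],
    )
    used_a, used_b, pairs = set(), set(), []
    for _, pa, pb in candidates:
        if pa in used_a or pb in used_b:
            continue
        pairs.append((pa, pb))
        used_a.add(pa)
        used_b.add(pb)
    lone_a = [p for p in a_pos if p not in used_a]
    lone_b = [p for p in b_pos if p not in used_b]
    return pairs, lone_a, lone_b


def molecules_for_assay(
    genotype: Genotype,
    assay: DuplexAssay,
    n_genomes: int,
    frag: FragmentationModel = INTACT_DNA,
    rng_seed: int | np.random.Generator | None = None,
) -> SpeciesCounts:
    """Fragment ``n_genomes`` copies of the genotype and count molecule
    species for one duplex assay.

    Every target locus contributes exactly one molecule per genome: a
    co-located pair that survives fragmentation is one doubly-marked
    molecule, a severed pair is one A-only plus one B-only molecule, and an
    unpaired locus is always a single. Targets absent from the genotype
    simply contribute zero counts.
    """
    if n_genomes <= 0:
        raise ValueError("n_genomes must be positive")
    rng = np.random.default_rng(rng_seed)
    a_only = b_only = linked = 0
    for h in genotype.haplotypes:
        pairs, lone_a, lone_b = _pair_loci(h, assay)
        a_only += len(lone_a) * n_genomes
        b_only += len(lone_b) * n_genomes
        for pa, pb in pairs:
            p_intact = frag.pair_intact_probability(pa, pb)
            n_linked = int(rng.binomial(n_genomes, p_intact))
            linked += n_linked
            a_only += n_genomes - n_linked
            b_only += n_genomes - n_linked
    return SpeciesCounts(a_only=a_only, b_only=b_only, linked_ab=linked)


def partition_into_droplets(
    species: SpeciesCounts,
    n_droplets: int,
    rng_seed: int | np.random.Generator | None = None,
    channel_a_name: str = "A",
    channel_b_name: str = "B",
    misclassification_rate: float = 0.0,
) -> QuadrantCounts:
    """Confine molecules into droplets uniformly at random and read out
    quadrant counts.

    A droplet is positive on a channel when it holds at least one molecule
    bearing that target; doubly-marked molecules light both channels.
    Droplet occupancy is not capped — positivity-by-occupancy reproduces
    Poisson statistics exactly. ``misclassification_rate`` optionally flips
    each channel read of each droplet ("rain"); the default is clean."""
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    rng = np.random.default_rng(rng_seed)
    a_pos = np.zeros(n_droplets, dtype=bool)
    b_pos = np.zeros(n_droplets, dtype=bool)
    if species.a_only:
        a_pos[rng.integers(0, n_droplets, size=species.a_only)] = True
    if species.b_only:
        b_pos[rng.integers(0, n_droplets, size=species.b_only)] = True
    if species.linked_ab:
        d = rng.integers(0, n_droplets, size=species.linked_ab)
        a_pos[d] = True
        b_pos[d] = True
    if misclassification_rate > 0:
        a_pos ^= rng.random(n_droplets) < misclassification_rate
        b_pos ^= rng.random(n_droplets) < misclassification_rate
    n_pp = int(np.sum(a_pos & b_pos))
    n_pn = int(np.sum(a_pos & ~b_pos))
    n_np = int(np.sum(~a_pos & b_pos))
    n_nn = n_droplets - n_pp - n_pn - n_np
    return QuadrantCounts(n_nn=n_nn, n_pn=n_pn, n_np=n_np, n_pp=n_pp,
                          channel_a_name=channel_a_name, channel_b_name=channel_b_name)


def simulate_duplex_well(
    genotype: Genotype,
    assay: DuplexAssay,
    n_genomes: int,
    n_droplets: int,
    frag: FragmentationModel = INTACT_DNA,
    rng_seed: int | np.random.Generator | None = None,
) -> QuadrantCounts:
    """Fragmentation plus confinement in one call."""
    rng = np.random.default_rng(rng_seed)
    species = molecules_for_assay(genotype, assay, n_genomes, frag, rng)
    return partition_into_droplets(species, n_droplets, rng,
                                   channel_a_name=assay.target_a,
                                   channel_b_name=assay.target_b)


def digestion_cut_sites(genotype: Genotype, assay: DuplexAssay,
                        cut_probability: float = 1.0) -> tuple:
    """Restriction sites at the midpoint of every co-located target pair,
    emulating complete (or partial) digestion between the linked loci."""
    sites = []
    for h in genotype.haplotypes:
        pairs, _, _ = _pair_loci(h, assay)
        for pa, pb in pairs:
            sites.append(((pa + pb) / 2.0, cut_probability))
    return tuple(sites)


def simulate_cnv_well(
    target_copies_per_genome: int,
    n_genomes: int,
    n_droplets: int,
    rng_seed: int | np.random.Generator | None = None,
    target_name: str = GENE_2DL5,
    reference_copies_per_genome: int = 2,
) -> QuadrantCounts:
    """Target-vs-RPP30 duplex well: unlinked molecules at the stated copy
    numbers per diploid genome (the reference contributes two)."""
    if not 0 <= target_copies_per_genome <= 4:
        raise ValueError("target copies per genome must be in [0, 4]")
    species = SpeciesCounts(
        a_only=target_copies_per_genome * n_genomes,
        b_only=reference_copies_per_genome * n_genomes,
        linked_ab=0,
    )
    return partition_into_droplets(species, n_droplets, rng_seed,
                                   channel_a_name=target_name,
                                   channel_b_name=GENE_RPP30)


@dataclass(frozen=True)
class SimulatedFamily:
    """A nuclear family with full genotypes and the derived call table."""

    family: FamilyGenotypes
    mother: Genotype
    father: Genotype
    children: tuple  # of Genotype


def _presence_pair(g: Genotype):
    return (g.carries(GENE_2DS3), g.carries(GENE_2DS5))


def simulate_family(
    mother: Genotype,
    father: Genotype,
    n_children: int,
    rng_seed: int | np.random.Generator | None = None,
    family_id: str = "FAM",
    gene: str = GENE_2DL5,
) -> SimulatedFamily:
    """Transmit one uniformly chosen haplotype from each parent per child and
    emit copy-number totals plus KIR2DS3/KIR2DS5 presence calls."""
    if n_children < 1:
        raise ValueError("need at least one child")
    rng = np.random.default_rng(rng_seed)
    children = tuple(
        Genotype(
            haplotype1=mother.haplotypes[rng.integers(2)],
            haplotype2=father.haplotypes[rng.integers(2)],
        )
        for _ in range(n_children)
    )
    child_ids = [f"{family_id}-C{i}" for i in range(n_children)]
    presence = {"mother": _presence_pair(mother), "father": _presence_pair(father)}
    for cid, c in zip(child_ids, children):
        presence[cid] = _presence_pair(c)
    fam = FamilyGenotypes(
        family_id=family_id,
        mother_cn=mother.count(gene),
        father_cn=father.count(gene),
        children_cn=[c.count(gene) for c in children],
        children_ids=child_ids,
        presence=presence,
    )
    return SimulatedFamily(family=fam, mother=mother, father=father, children=children)
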