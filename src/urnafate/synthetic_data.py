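"""Birth-death simulation of multicopy ncRNA evolution along a species tree.

The generator embodies the retrotransposition model the pipeline is built
to interrogate: functional ncRNA copies seed new genomic copies at a
constant birth rate per unit branch length; each new copy either lands with
a working pol-II promoter (probability ``promoter_capture_prob``) and
becomes a functional source itself, or is dead on arrival (DOA) and decays
until it is no longer annotatable (rate ``death_rate``).  New copies carry
a 3' poly-A remnant whose adenosines substitute away over time; DOA copies
accumulate substitutions at the neutral rate while functional copies are
constrained by purifying selection.

From the simulated history the generator materializes every input file the
analysis consumes - per-species annotations and genomes, a noiseless (or
optionally lossy) alignment-block map, pol-II ChIP peaks per cell line,
per-read alignment tables with truthful multi-mapping, CAGE peaks with tag
counts, covariance-model score tables, and population variant calls - plus
a ground-truth table of origin nodes and functional labels.

Structural randomness (births, promoter capture, DOA lifetimes) and
sequence-level randomness (substitutions, tail decay) are drawn from
separate streams derived from one seed, so sweeping ``death_rate`` or
``polya_decay_rate`` over a grid with a fixed seed yields histories coupled
by common random numbers: presence sets shrink monotonically with the death
rate and surviving poly-A tails shrink monotonically with the decay rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io_formats
from .dollo import label_internal_nodes, node_label
from .expression import CagePeak
from .io_formats import (
    CmHit,
    GenomicInterval,
    NcRnaLocus,
    ReadAlignmentRecord,
    VariantRecord,
)
from .synteny import AlignmentMap

DEFAULT_FAMILIES = ("U1", "U2", "U3", "U4", "U5", "U6")

#: A 6-leaf amniote-like tree, depth 4 time units, labeled internal nodes.
DEFAULT_TREE_NEWICK = (
    "(((human:0.5,chimp:0.5)primate:1.5,(mouse:1.0,rat:1.0)rodent:1.0)mammal:2.0,"
    "chicken:4.0)amniote;"
)

DEFAULT_CLADE_LABELS = {
    "human": "species-specific",
    "primate": "primate",
    "rodent": "rodent",
    "mammal": "mammal",
    "amniote": "amniote",
}

_BASES = "ACGT"


class ParameterError(ValueError):
    pass


@dataclasses.dataclass
class SimParams:
    """Rates and sizes of the simulated birth-death process.

    Rates are per unit branch length; the tree's branch lengths set the
    time scale.  Defaults portray the regime the pipeline targets: a couple
    of ancient functional copies per family, ongoing retrotransposition,
    and fast decay of DOA copies.
    """

    birth_rate: float = 0.4
    death_rate: float = 0.5
    promoter_capture_prob: float = 0.25
    polya_init_len: int = 30
    polya_decay_rate: float = 0.1
    subst_rate: float = 0.02          # per site per unit time, neutral
    functional_constraint: float = 0.1  # multiplier on subst_rate for functional loci
    locus_len: int = 150
    genome_len: int = 0               # 0 = sized automatically from copy count
    n_root_loci: int = 2              # ancestral functional copies per family
    families: Sequence[str] = DEFAULT_FAMILIES
    n_cell_lines: int = 7
    promoter_detect_prob: float = 1.0
    cm_base_score: float = 170.0
    cm_penalty_per_sub: float = 2.0
    variant_mean_functional: float = 1.5
    variant_mean_doa: float = 5.0
    map_drop_prob: float = 0.0        # per-block chance of being absent from the map
    cross_map_noise: float = 0.0      # DOA noise reads as fraction of mean depth
    multimap_max_mismatches: int = 3  # paralog distance that can trigger multi-mapping
    read_len: int = 50
    seed: int = 0

    def validate(self) -> None:
        for name in ("birth_rate", "death_rate", "polya_decay_rate", "subst_rate",
                     "functional_constraint", "cross_map_noise", "map_drop_prob"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("promoter_capture_prob", "promoter_detect_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0,1]")
        if self.n_root_loci < 1 or self.locus_len < 10:
            raise ParameterError("need n_root_loci >= 1 and locus_len >= 10")


@dataclasses.dataclass
class Lineage:
    """One copy lineage: born once, present in every descendant species
    that it reaches before (DOA only) its sequence decays away."""

    lid: int
    family: str
    functional: bool
    origin_node: str
    birth_depth: float
    death_depth: float  # absolute depth at which a DOA lineage dies (inf = never)
    strand: str
    slot: int


@dataclasses.dataclass
class SimulatedDataset:
    """A simulated family history plus every emitted pipeline input."""

    tree: object
    params: SimParams
    lineages: dict[str, dict[int, Lineage]]          # family -> lid -> lineage
    presence: dict[str, dict[str, list[int]]]        # family -> species -> [lid]
    loci: dict[str, list[NcRnaLocus]]                # species -> loci (all families)
    locus_seqs: dict[tuple[str, str], str]           # (species, locus_id) -> core seq
    locus_tails: dict[tuple[str, str], str]          # (species, locus_id) -> tail seq
    genomes: dict[str, dict[str, str]]               # species -> chrom -> sequence
    alignment_map: AlignmentMap
    polii_peaks: dict[str, dict[str, list[GenomicInterval]]]  # sp -> cell line -> peaks
    cm_hits: dict[str, list[CmHit]]
    variants: dict[str, list[VariantRecord]]
    truth: "object"                                   # pandas DataFrame
    reads: dict[str, list[ReadAlignmentRecord]] = dataclasses.field(default_factory=dict)
    cage_peaks: dict[str, list[CagePeak]] = dataclasses.field(default_factory=dict)
    pc_tss: dict[str, list[tuple[str, int, str]]] = dataclasses.field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return [node_label(leaf) for leaf in self.tree.leaf_node_iter()]

    def locus_by_id(self, species: str, locus_id: str) -> NcRnaLocus:
        for l in self.loci[species]:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)


def default_tree():
    tree = io_formats.read_newick_rooted(DEFAULT_TREE_NEWICK)
    label_internal_nodes(tree)
    return tree


def _locus_id(family: str, lid: int) -> str:
    return f"{family}.L{lid}"


def _chrom_of(family: str) -> str:
    return f"chr_{family}"


def _mutate(seq: list[str], n_subs: int, rng) -> None:
    """Apply n JC-style substitutions at random sites (multiple hits allowed)."""
    length = len(seq)
    for _ in range(n_subs):
        pos = int(rng.integers(0, length))
        others = [b for b in _BASES if b != seq[pos]]
        seq[pos] = others[int(rng.integers(0, 3))]


def simulate_family_evolution(tree, params: SimParams) -> SimulatedDataset:
    """Simulate all families along the tree and materialize every input.

    The structural process per family: ``n_root_loci`` functional copies
    exist at the root; along every branch each functional copy spawns new
    copies as a Poisson process at ``birth_rate``, each new copy functional
    with ``promoter_capture_prob`` (functional copies spawn recursively
    within the branch); a DOA copy's annotatable lifetime is exponential
    with rate ``death_rate``.  A warning-level static dataset (no events)
    results when all rates are zero.
    """
    params.validate()
    import pandas as pd

    if params.birth_rate == 0.0 and params.death_rate == 0.0 and params.subst_rate == 0.0:
        import warnings

        warnings.warn("all rates are zero: dataset is static", stacklevel=2)
    label_internal_nodes(tree)
    depths: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[id(node)] = 0.0
        else:
            depths[id(node)] = depths[id(node.parent_node)] + (node.edge.length or 0.0)

    rng_events = np.random.default_rng([params.seed, 11])
    rng_seq = np.random.default_rng([params.seed, 12])
    rng_tail = np.random.default_rng([params.seed, 13])
    rng_var = np.random.default_rng([params.seed, 14])
    rng_prom = np.random.default_rng([params.seed, 15])
    rng_root = np.random.default_rng([params.seed, 16])
    rng_map = np.random.default_rng([params.seed, 17])

    root_label = node_label(tree.seed_node)
    leaves = [node_label(l) for l in tree.leaf_node_iter()]

    families = list(params.families)
    root_seqs = {
        fam: "".join(_BASES[i] for i in rng_root.integers(0, 4, size=params.locus_len))
        for fam in families
    }

    lineages: dict[str, dict[int, Lineage]] = {fam: {} for fam in families}
    presence: dict[str, dict[str, list[int]]] = {fam: {sp: [] for sp in leaves} for fam in families}

    for fam in families:
        counter = [0]

        def new_lineage(functional: bool, origin: str, birth_depth: float) -> Lineage:
            lid = counter[0]
            counter[0] += 1
            strand = "+" if rng_events.random() < 0.5 else "-"
            # lifetime drawn unconditionally so death_rate sweeps stay coupled
            e = float(rng_events.exponential(1.0))
            if functional or params.death_rate == 0.0:
                death_depth = math.inf
            else:
                death_depth = birth_depth + e / params.death_rate
            lin = Lineage(
                lid=lid, family=fam, functional=functional, origin_node=origin,
                birth_depth=birth_depth, death_depth=death_depth, strand=strand, slot=lid,
            )
            lineages[fam][lid] = lin
            return lin

        def spawn(t_birth_window_start: float, window: float, child_label: str,
                  child_end_depth: float, out: list[int]) -> None:
            """Births by one functional copy over ``window`` time units ending
            at ``child_end_depth``; functional children spawn recursively."""
            if params.birth_rate == 0.0 or window <= 0:
                return
            n = int(rng_events.poisson(params.birth_rate * window))
            if n == 0:
                return
            times = np.sort(rng_events.uniform(0.0, window, size=n))
            for t in times:
                birth_depth = t_birth_window_start + float(t)
                functional = bool(rng_events.random() < params.promoter_capture_prob)
                lin = new_lineage(functional, child_label, birth_depth)
                remaining = child_end_depth - birth_depth
                if functional:
                    out.append(lin.lid)
                    spawn(birth_depth, remaining, child_label, child_end_depth, out)
                else:
                    if lin.death_depth > child_end_depth:
                        out.append(lin.lid)

        def process(node, active: list[int]) -> None:
            if node.is_leaf():
                presence[fam][node_label(node)] = list(active)
                return
            for child in node.child_nodes():
                child_label = node_label(child)
                t0 = depths[id(node)]
                t1 = depths[id(child)]
                child_active: list[int] = []
                for lid in active:
                    lin = lineages[fam][lid]
                    if lin.functional:
                        child_active.append(lid)
                        spawn(t0, t1 - t0, child_label, t1, child_active)
                    elif lin.death_depth > t1:
                        child_active.append(lid)
                process(child, child_active)

        roots = [new_lineage(True, root_label, 0.0).lid for _ in range(params.n_root_loci)]
        process(tree.seed_node, roots)

    # ------------------------------------------------------------------
    # Materialize loci, sequences, tails, genomes, per-locus evidence
    # ------------------------------------------------------------------
    loci: dict[str, list[NcRnaLocus]] = {sp: [] for sp in leaves}
    locus_seqs: dict[tuple[str, str], str] = {}
    locus_tails: dict[tuple[str, str], str] = {}
    cm_hits: dict[str, list[CmHit]] = {sp: [] for sp in leaves}
    variants: dict[str, list[VariantRecord]] = {sp: [] for sp in leaves}
    truth_rows = []

    leaf_depth = {node_label(l): depths[id(l)] for l in tree.leaf_node_iter()}
    c = params.functional_constraint

    for sp in leaves:
        for fam in families:
            root_seq = root_seqs[fam]
            for lid in sorted(presence[fam][sp]):
                lin = lineages[fam][lid]
                tau = leaf_depth[sp] - lin.birth_depth
                # substitutions: constrained before birth (functional source
                # history), then constrained or neutral depending on fate
                rate_after = params.subst_rate * (c if lin.functional else 1.0)
                lam = params.locus_len * (
                    params.subst_rate * c * lin.birth_depth + rate_after * tau
                )
                n_subs = int(rng_seq.poisson(lam))
                seq = list(root_seq)
                _mutate(seq, n_subs, rng_seq)
                seq_s = "".join(seq)
                # poly-A tail: root copies are not retrocopies and carry none
                tail_chars = []
                if lin.origin_node != root_label:
                    p_flip = 1.0 - math.exp(-params.polya_decay_rate * tau)
                    for _ in range(params.polya_init_len):
                        u = float(rng_tail.random())
                        alt = "CGT"[int(rng_tail.integers(0, 3))]
                        tail_chars.append(alt if u < p_flip else "A")
                tail_s = "".join(tail_chars)

                locus_id = _locus_id(fam, lid)
                start = 500 + lin.slot * 1000
                iv = GenomicInterval(_chrom_of(fam), start, start + params.locus_len, lin.strand)
                locus = NcRnaLocus(
                    interval=iv, species=sp, family=fam, locus_id=locus_id, biotype="snRNA"
                )
                loci[sp].append(locus)
                locus_seqs[(sp, locus_id)] = seq_s
                locus_tails[(sp, locus_id)] = tail_s

                dist = sum(1 for a, b in zip(seq_s, root_seq) if a != b)
                cm_hits[sp].append(
                    CmHit(
                        locus_id=locus_id,
                        cm_score=params.cm_base_score - params.cm_penalty_per_sub * dist,
                        family=fam,
                    )
                )
                truth_rows.append(
                    {
                        "species": sp,
                        "locus_id": locus_id,
                        "family": fam,
                        "lineage": lid,
                        "origin_node": lin.origin_node,
                        "functional": lin.functional,
                        "birth_depth": lin.birth_depth,
                        "strand": lin.strand,
                        "tail_a_remaining": tail_s.count("A"),
                        "n_substitutions": dist,
                    }
                )

    # genomes: random background per species, loci + tails implanted
    genomes: dict[str, dict[str, str]] = {}
    for si, sp in enumerate(leaves):
        rng_genome = np.random.default_rng([params.seed, 18, si])
        chroms: dict[str, str] = {}
        for fam in families:
            n_slots = max((lineages[fam][lid].slot for lid in lineages[fam]), default=0) + 1
            length = max(params.genome_len, 1000 + n_slots * 1000)
            arr = rng_genome.integers(0, 4, size=length)
            chrom = [_BASES[i] for i in arr]
            for locus in loci[sp]:
                if locus.family != fam:
                    continue
                iv = locus.interval
                seq = locus_seqs[(sp, locus.locus_id)]
                tail = locus_tails[(sp, locus.locus_id)]
                if iv.strand == "+":
                    chrom[iv.start:iv.end] = list(seq)
                    chrom[iv.end:iv.end + len(tail)] = list(tail)
                else:
                    from .retro_signatures import reverse_complement

                    chrom[iv.start:iv.end] = list(reverse_complement(seq))
                    rc_tail = reverse_complement(tail)
                    chrom[iv.start - len(tail):iv.start] = list(rc_tail)
            chroms[_chrom_of(fam)] = "".join(chrom)
        genomes[sp] = chroms

    # alignment map: one block per lineage over its carrying species
    blocks: dict[str, dict[str, GenomicInterval]] = {}
    for fam in families:
        for lid, lin in sorted(lineages[fam].items()):
            carriers = [sp for sp in leaves if lid in presence[fam][sp]]
            if len(carriers) == 0:
                continue
            if params.map_drop_prob > 0 and rng_map.random() < params.map_drop_prob:
                continue
            start = 500 + lin.slot * 1000
            iv = GenomicInterval(
                _chrom_of(fam), max(0, start - 200), start + params.locus_len + 200, "+"
            )
            blocks[f"{fam}.b{lid}"] = {sp: iv for sp in carriers}
    alignment_map = AlignmentMap(blocks)

    # pol-II peaks per cell line: functional loci captured with detect prob
    polii: dict[str, dict[str, list[GenomicInterval]]] = {}
    cell_lines = [f"cell{i}" for i in range(params.n_cell_lines)]
    for sp in leaves:
        polii[sp] = {cl: [] for cl in cell_lines}
        for locus in loci[sp]:
            lin = lineages[locus.family][int(locus.locus_id.split(".L")[1])]
            for cl in cell_lines:
                u = float(rng_prom.random())  # drawn for every locus: keeps streams aligned
                if not lin.functional:
                    continue
                if u < params.promoter_detect_prob:
                    tss = locus.tss
                    polii[sp][cl].append(
                        GenomicInterval(locus.interval.chrom, max(0, tss - 100), tss + 100, ".")
                    )

    # population variants: DOA loci carry a heavier segregating load
    populations = list(io_formats.DEFAULT_POPULATIONS)
    for sp in leaves:
        for locus in loci[sp]:
            lin = lineages[locus.family][int(locus.locus_id.split(".L")[1])]
            mean = params.variant_mean_functional if lin.functional else params.variant_mean_doa
            n = int(rng_var.poisson(mean))
            iv = locus.interval
            for _ in range(n):
                pos = int(rng_var.integers(iv.start + 1, iv.end + 1))  # 1-based
                ref = genomes[sp][iv.chrom][pos - 1]
                alt = [b for b in _BASES if b != ref][int(rng_var.integers(0, 3))]
                pop = populations[int(rng_var.integers(0, len(populations)))]
                af = float(rng_var.uniform(0.01, 0.3))
                pop_af = {p: (af if p == pop else 0.0) for p in populations}
                variants[sp].append(
                    VariantRecord(chrom=iv.chrom, pos=pos, ref=ref, alt=alt, pop_af=pop_af)
                )
        variants[sp].sort(key=lambda v: (v.chrom, v.pos))

    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        tree=tree,
        params=params,
        lineages=lineages,
        presence=presence,
        loci=loci,
        locus_seqs=locus_seqs,
        locus_tails=locus_tails,
        genomes=genomes,
        alignment_map=alignment_map,
        polii_peaks=polii,
        cm_hits=cm_hits,
        variants=variants,
        truth=truth,
    )


def simulate_expression(
    ds: SimulatedDataset,
    mean_depth: float = 60.0,
    n_samples: int = 4,
    seed: int = 0,
    cage_mean: float = 50.0,
) -> SimulatedDataset:
    """Draw per-sample RNA-seq reads and CAGE tags for functional loci.

    Functional loci receive Poisson(``mean_depth``) reads per sample; a
    read from a locus with a same-family paralog within
    ``multimap_max_mismatches`` is emitted multi-mapped with probability
    equal to the sequence identity to its closest such paralog.  DOA loci
    receive zero true expression, plus optional unique-looking
    cross-mapping noise at rate ``params.cross_map_noise``.  CAGE peaks sit
    on each functional locus's 5' end with Poisson(``cage_mean``) tags.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    params = ds.params
    rng = np.random.default_rng([seed, 21])
    samples = [f"s{i}" for i in range(n_samples)]
    k = params.multimap_max_mismatches
    L = params.locus_len
    read_len = min(params.read_len, L)

    functional_of: dict[tuple[str, str], bool] = {}
    for _, row in ds.truth.iterrows():
        functional_of[(row["species"], row["locus_id"])] = bool(row["functional"])

    for sp in ds.species:
        sp_loci = ds.loci[sp]
        # pairwise distances within each family for multi-mapping truth
        by_family: dict[str, list[NcRnaLocus]] = {}
        for l in sp_loci:
            by_family.setdefault(l.family, []).append(l)
        close_paralogs: dict[str, tuple[int, int]] = {}  # locus -> (min_dist, n_within_k)
        for fam, fam_loci in by_family.items():
            seqs = {l.locus_id: ds.locus_seqs[(sp, l.locus_id)] for l in fam_loci}
            for l in fam_loci:
                dmin, nk = L + 1, 0
                for other in fam_loci:
                    if other.locus_id == l.locus_id:
                        continue
                    d = sum(1 for a, b in zip(seqs[l.locus_id], seqs[other.locus_id]) if a != b)
                    if d < dmin:
                        dmin = d
                    if d <= k:
                        nk += 1
                close_paralogs[l.locus_id] = (dmin, nk)

        reads: list[ReadAlignmentRecord] = []
        cage: list[CagePeak] = []
        ridx = 0
        for locus in sp_loci:
            functional = functional_of[(sp, locus.locus_id)]
            iv = locus.interval
            dmin, nk = close_paralogs[locus.locus_id]
            p_multi = (1.0 - dmin / L) if (dmin <= k and nk > 0) else 0.0
            for sample in samples:
                if functional:
                    n_reads = int(rng.poisson(mean_depth))
                else:
                    n_reads = (
                        int(rng.poisson(params.cross_map_noise * mean_depth))
                        if params.cross_map_noise > 0
                        else 0
                    )
                for _ in range(n_reads):
                    start = int(rng.integers(iv.start, max(iv.start + 1, iv.end - read_len + 1)))
                    end = min(start + read_len, iv.end)
                    multi = functional and p_multi > 0 and rng.random() < p_multi
                    n_hits = 1 + nk if multi else 1
                    reads.append(
                        ReadAlignmentRecord(
                            read_id=f"{sp}.r{ridx}",
                            sample=sample,
                            interval=GenomicInterval(iv.chrom, start, end, "."),
                            n_hits=n_hits,
                        )
                    )
                    ridx += 1
            if functional:
                tss = locus.tss
                if iv.strand == "+":
                    peak_iv = GenomicInterval(iv.chrom, tss, tss + 24, "+")
                else:
                    peak_iv = GenomicInterval(iv.chrom, max(0, tss - 23), tss + 1, "-")
                counts = {s: int(rng.poisson(cage_mean)) for s in samples}
                cage.append(CagePeak(interval=peak_iv, counts=counts))
        ds.reads[sp] = reads
        ds.cage_peaks[sp] = cage
        ds.pc_tss.setdefault(sp, [])
    return ds


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def emit_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write every pipeline input file plus the truth table.

    Returns a manifest mapping relative paths to sha256 digests; the same
    dataset always emits byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "polii").mkdir(exist_ok=True)
    written: list[Path] = []

    tree_path = out / "tree.nwk"
    tree_path.write_text(
        ds.tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    )
    written.append(tree_path)

    ds.alignment_map.to_tsv(out / "blocks.tsv")
    written.append(out / "blocks.tsv")

    for sp in ds.species:
        gff = out / f"{sp}.gff3"
        io_formats.write_gff3(gff, ds.loci[sp])
        written.append(gff)

        fa = out / f"{sp}.fa"
        io_formats.write_fasta(fa, ds.genomes[sp])
        written.append(fa)

        for cl in sorted(ds.polii_peaks[sp]):
            bed = out / "polii" / f"{sp}.{cl}.bed"
            io_formats.write_bed(
                bed, [(iv, f"{cl}.p{i}", 0.0) for i, iv in enumerate(ds.polii_peaks[sp][cl])]
            )
            written.append(bed)

        tbl = out / f"{sp}.cm.tblout"
        io_formats.write_tblout(tbl, ds.cm_hits[sp])
        written.append(tbl)

        vcf = out / f"{sp}.vcf"
        io_formats.write_vcf(vcf, ds.variants[sp])
        written.append(vcf)

        if sp in ds.reads:
            rt = out / f"{sp}.reads.tsv"
            io_formats.write_alignment_tsv(rt, ds.reads[sp])
            written.append(rt)
        if sp in ds.cage_peaks:
            ct = out / f"{sp}.cage.tsv"
            _write_cage_tsv(ct, ds.cage_peaks[sp])
            written.append(ct)

    truth_path = out / "truth.tsv"
    ds.truth.to_csv(truth_path, sep="\t", index=False)
    written.append(truth_path)

    manifest = {str(p.relative_to(out)): _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_cage_tsv(path: Path, peaks: Sequence[CagePeak]) -> None:
    samples: list[str] = []
    for p in peaks:
        for s in p.counts:
            if s not in samples:
                samples.append(s)
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\t" + "\t".join(samples) + "\n")
        for p in peaks:
            iv = p.interval
            row = "\t".join(str(p.counts.get(s, 0)) for s in samples)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{row}\n")


def read_cage_tsv(path: str | Path) -> list[CagePeak]:
    peaks = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[4:]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                continue
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[3])
            counts = {s: int(v) for s, v in zip(samples, f[4:])}
            peaks.append(CagePeak(interval=iv, counts=counts))
    return peaks
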