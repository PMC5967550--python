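"""Cross-species synteny grouping of same-family ncRNA loci.

Loci from different species are grouped when they occupy corresponding
positions under a whole-genome-alignment block map.  Grouping follows a
greedy seed-and-remove rule: iterate species in a fixed order, take each
still-unassigned locus as a seed, pull in every same-family locus from the
other species whose alignment projection overlaps the seed by >=1 bp, and
remove all of them from the search space so later seeds cannot claim them
reciprocally.  Loci that match nothing become singleton groups; the output
partitions the input.

By default expansion is one hop from the seed only.  ``transitive=True``
instead computes connected components of the pairwise-overlap graph.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import FormatError, GenomicInterval, NcRnaLocus


@dataclasses.dataclass(frozen=True)
class SyntenyGroup:
    """A set of loci across species occupying corresponding positions."""

    group_id: str
    members: frozenset[tuple[str, str]]  # (species, locus_id)
    family: str


class AlignmentMap:
    """Orthology blocks with offset-preserving per-species coordinates.

    Each block maps species to one interval; within a block the coordinate
    correspondence is offset-preserving from the block start (reversed for
    blocks whose strands disagree).
    """

    def __init__(self, blocks: Mapping[str, Mapping[str, GenomicInterval]]):
        self.blocks: dict[str, dict[str, GenomicInterval]] = {
            bid: dict(sp_map) for bid, sp_map in blocks.items()
        }
        # per-species index of (interval, block_id), sorted for determinism
        self._by_species: dict[str, list[tuple[GenomicInterval, str]]] = defaultdict(list)
        for bid in sorted(self.blocks):
            for sp, iv in self.blocks[bid].items():
                self._by_species[sp].append((iv, bid))
        for sp in self._by_species:
            self._by_species[sp].sort(key=lambda t: (t[0].chrom, t[0].start, t[1]))

    @property
    def species(self) -> set[str]:
        return set(self._by_species)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlignmentMap":
        """Load from TSV: block_id, species, chrom, start, end, strand."""
        blocks: dict[str, dict[str, GenomicInterval]] = defaultdict(dict)
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#") or line.startswith("block_id\t"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 6:
                    raise FormatError(f"alignment map line {i}: need 6 columns")
                bid, sp = f[0], f[1]
                if sp in blocks[bid]:
                    raise FormatError(f"block {bid}: species {sp} appears twice")
                blocks[bid][sp] = GenomicInterval(f[2], int(f[3]), int(f[4]), f[5])
        return cls(blocks)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("block_id\tspecies\tchrom\tstart\tend\tstrand\n")
            for bid in sorted(self.blocks):
                for sp in sorted(self.blocks[bid]):
                    iv = self.blocks[bid][sp]
                    fh.write(f"{bid}\t{sp}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")

    def project_interval(
        self, species: str, iv: GenomicInterval, target: str
    ) -> GenomicInterval | None:
        """Project ``iv`` from ``species`` onto ``target`` coordinates.

        Returns the projection of the part of ``iv`` overlapping a block
        that carries both species, or None if no such block overlaps.  An
        interval straddling a block edge projects only its in-block part.
        """
        if species not in self._by_species:
            raise KeyError(f"unknown species {species!r} in alignment map")
        for src_iv, bid in self._by_species[species]:
            if not src_iv.overlaps(iv):
                continue
            tgt_iv = self.blocks[bid].get(target)
            if tgt_iv is None:
                continue
            ov_start = max(iv.start, src_iv.start)
            ov_end = min(iv.end, src_iv.end)
            off = ov_start - src_iv.start
            length = ov_end - ov_start
            if src_iv.strand == tgt_iv.strand or "." in (src_iv.strand, tgt_iv.strand):
                t_start = tgt_iv.start + off
                t_end = t_start + length
            else:  # orientation flip within the block
                t_end = tgt_iv.end - off
                t_start = t_end - length
            t_start = max(t_start, tgt_iv.start)
            t_end = min(t_end, tgt_iv.end)
            if t_start >= t_end:
                continue
            return GenomicInterval(tgt_iv.chrom, t_start, t_end, tgt_iv.strand)
        return None


def _sorted_loci(loci: Iterable[NcRnaLocus]) -> list[NcRnaLocus]:
    return sorted(loci, key=lambda l: (l.interval.chrom, l.interval.start, l.locus_id))


def build_synteny_groups(
    loci_by_species: Mapping[str, Sequence[NcRnaLocus]],
    amap: AlignmentMap,
    family: str,
    species_order: Sequence[str] | None = None,
    transitive: bool = False,
) -> list[SyntenyGroup]:
    """Greedily partition same-family loci into cross-species synteny groups.

    ``species_order`` fixes the seed iteration order (default: sorted
    species names; pipelines pass the tree's leaf order).  Within a species,
    seeds are visited in (chrom, start, locus_id) order.
    """
    for sp, loci in loci_by_species.items():
        ids = [l.locus_id for l in loci]
        if len(ids) != len(set(ids)):
            raise FormatError(f"duplicate locus_id within species {sp}")
        for l in loci:
            if l.family != family:
                raise FormatError(
                    f"locus {l.locus_id} has family {l.family}, expected {family}"
                )

    if species_order is None:
        species_order = sorted(loci_by_species)
    ordered = {sp: _sorted_loci(loci_by_species.get(sp, [])) for sp in species_order}

    if transitive:
        return _connected_component_groups(ordered, amap, family, species_order)

    assigned: set[tuple[str, str]] = set()
    groups: list[SyntenyGroup] = []
    gid = 0
    for seed_sp in species_order:
        for seed in ordered[seed_sp]:
            key = (seed_sp, seed.locus_id)
            if key in assigned:
                continue
            members = {key}
            assigned.add(key)
            for other_sp in species_order:
                if other_sp == seed_sp:
                    continue
                proj = amap.project_interval(seed_sp, seed.interval, other_sp)
                if proj is None:
                    continue
                for cand in ordered[other_sp]:
                    ckey = (other_sp, cand.locus_id)
                    if ckey in assigned:
                        continue
                    if cand.interval.overlaps(proj):
                        members.add(ckey)
                        assigned.add(ckey)
            groups.append(
                SyntenyGroup(group_id=f"{family}.g{gid}", members=frozenset(members), family=family)
            )
            gid += 1
    return groups


def _connected_component_groups(
    ordered: Mapping[str, Sequence[NcRnaLocus]],
    amap: AlignmentMap,
    family: str,
    species_order: Sequence[str],
) -> list[SyntenyGroup]:
    """Transitive variant: connected components of the projection-overlap graph."""
    keys: list[tuple[str, str]] = []
    locus_of: dict[tuple[str, str], NcRnaLocus] = {}
    for sp in species_order:
        for l in ordered[sp]:
            keys.append((sp, l.locus_id))
            locus_of[(sp, l.locus_id)] = l
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for sp_a in species_order:
        for la in ordered[sp_a]:
            for sp_b in species_order:
                if sp_b == sp_a:
                    continue
                proj = amap.project_interval(sp_a, la.interval, sp_b)
                if proj is None:
                    continue
                for lb in ordered[sp_b]:
                    if lb.interval.overlaps(proj):
                        union((sp_a, la.locus_id), (sp_b, lb.locus_id))

    comps: dict[tuple[str, str], set[tuple[str, str]]] = defaultdict(set)
    for k in keys:
        comps[find(k)].add(k)
    groups = []
    for gid, root in enumerate(sorted(comps)):
        groups.append(
            SyntenyGroup(group_id=f"{family}.g{gid}", members=frozenset(comps[root]), family=family)
        )
    return groups


def write_groups_tsv(path: str | Path, groups: Iterable[SyntenyGroup]) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tfamily\tspecies\tlocus_id\n")
        for g in groups:
            for sp, lid in sorted(g.members):
                fh.write(f"{g.group_id}\t{g.family}\t{sp}\t{lid}\n")


def read_groups_tsv(path: str | Path) -> list[SyntenyGroup]:
    by_gid: dict[str, tuple[str, set[tuple[str, str]]]] = {}
    for f in _body_rows(path):
        gid, fam, sp, lid = f[0], f[1], f[2], f[3]
        if gid not in by_gid:
            by_gid[gid] = (fam, set())
        by_gid[gid][1].add((sp, lid))
    return [
        SyntenyGroup(group_id=gid, members=frozenset(mem), family=fam)
        for gid, (fam, mem) in sorted(by_gid.items())
    ]


def _body_rows(path: str | Path):
    with open(path) as fh:
        first = True
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if first:
                first = False
                if f[0] == "group_id":
                    continue
            yield f
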