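"""End-to-end pipeline: simulate -> synteny -> Dollo -> signatures ->
expression -> evidence, with a single YAML-loadable configuration.

Every stage is importable on its own; :func:`run_all` chains them on a
simulated dataset and writes one report directory with per-species
evidence tables, summary tables and a JSON manifest of digests.  The run
is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import divergence, dollo, evidence, expression, io_formats, retro_signatures, synteny
from .synthetic_data import (
    DEFAULT_CLADE_LABELS,
    SimParams,
    SimulatedDataset,
    default_tree,
    emit_dataset,
    simulate_expression,
    simulate_family_evolution,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    Window sizes are inclusive bp distances; the poly-A flag is strict
    (a_fraction must exceed ``polya_threshold``); ``expression_min_count``
    is the count a locus must exceed in at least one retained sample to be
    called expressed.
    """

    seed: int = 0
    tree: str | None = None              # Newick path; None = built-in 6-leaf tree
    sim: dict[str, Any] = dataclasses.field(default_factory=dict)  # SimParams overrides
    polii_window: int = 500
    cage_window: int = 500
    polya_flank: int = 30
    polya_threshold: float = 0.5
    repeat_flank: int = 100
    expression_min_count: float = 0.0
    ks_method: str = "asymptotic"
    transitive_synteny: bool = False
    cage_iterate: bool = False
    reference_species: str = "human"
    mean_depth: float = 60.0
    n_samples: int = 4
    cage_mean: float = 50.0
    clade_labels: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLADE_LABELS)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def sim_params(self) -> SimParams:
        params = SimParams(seed=self.seed)
        for key, value in self.sim.items():
            if not hasattr(params, key):
                raise ValueError(f"unknown sim parameter {key!r}")
            setattr(params, key, value)
        params.seed = self.seed
        return params


# ---------------------------------------------------------------------------
# Stage wrappers (used by run_all and by the CLI subcommands)
# ---------------------------------------------------------------------------

def simulate_stage(config: PipelineConfig) -> SimulatedDataset:
    tree = (
        io_formats.read_newick_rooted(config.tree) if config.tree else default_tree()
    )
    dollo.label_internal_nodes(tree)
    ds = simulate_family_evolution(tree, config.sim_params())
    simulate_expression(
        ds,
        mean_depth=config.mean_depth,
        n_samples=config.n_samples,
        seed=config.seed,
        cage_mean=config.cage_mean,
    )
    return ds


def synteny_stage(ds: SimulatedDataset, config: PipelineConfig) -> list[synteny.SyntenyGroup]:
    species_order = ds.species
    groups: list[synteny.SyntenyGroup] = []
    for family in ds.params.families:
        loci_by_species = {
            sp: [l for l in ds.loci[sp] if l.family == family] for sp in species_order
        }
        groups.extend(
            synteny.build_synteny_groups(
                loci_by_species,
                ds.alignment_map,
                family,
                species_order=species_order,
                transitive=config.transitive_synteny,
            )
        )
    return groups


def dollo_stage(
    ds: SimulatedDataset,
    groups: list[synteny.SyntenyGroup],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, dollo.DolloReconstruction], dict[str, dict[str, str]]]:
    """Presence/absence matrix, per-group reconstructions, and per-species
    per-locus depth labels."""
    matrix = dollo.to_presence_absence(groups, ds.species)
    recs = {r.group_id: r for r in dollo.reconstruct_matrix(matrix, ds.tree)}
    group_of: dict[tuple[str, str], str] = {}
    for g in groups:
        for sp, lid in g.members:
            group_of[(sp, lid)] = g.group_id
    depth_labels: dict[str, dict[str, str]] = {}
    for sp in ds.species:
        labels = dict(config.clade_labels)
        labels[sp] = "species-specific"
        per_locus = {}
        for locus in ds.loci[sp]:
            gid = group_of[(sp, locus.locus_id)]
            per_locus[locus.locus_id] = dollo.conservation_depth(
                recs[gid], ds.tree, reference=sp, clade_labels=labels
            )
        depth_labels[sp] = per_locus
    return matrix, recs, depth_labels


def signatures_stage(ds: SimulatedDataset, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    return {
        sp: retro_signatures.polya_table(
            ds.genomes[sp],
            ds.loci[sp],
            flank_len=config.polya_flank,
            threshold=config.polya_threshold,
        )
        for sp in ds.species
    }


def expression_stage(
    ds: SimulatedDataset, config: PipelineConfig
) -> dict[str, dict[str, Any]]:
    """Per-species promoter, RNA-seq and CAGE evidence."""
    out: dict[str, dict[str, Any]] = {}
    for sp in ds.species:
        loci = ds.loci[sp]
        prom = expression.promoter_table(loci, ds.polii_peaks[sp], window=config.polii_window)
        counts, libsize = expression.count_unique_reads(ds.reads.get(sp, []), loci)
        if (libsize > 0).all() and len(libsize):
            lengths = {l.locus_id: len(l.interval) for l in loci}
            rpkms = expression.rpkm_matrix(counts, libsize, lengths)
        else:
            rpkms = counts.astype(float)
        rnaseq_expressed = expression.expressed_flags(counts, config.expression_min_count)
        cage_raw = expression.assign_cage_peaks(
            ds.cage_peaks.get(sp, []), loci, ds.pc_tss.get(sp, []), window=config.cage_window
        )
        cage_filtered = expression.filter_cage_matrix(cage_raw, iterate=config.cage_iterate)
        if cage_filtered.shape[1] >= 2 and not cage_filtered.empty:
            factors = expression.tmm_factors(cage_filtered)
            cage_tpm = expression.tmm_tpm(cage_filtered, factors)
        else:
            factors = None
            cage_tpm = cage_filtered.astype(float)
        cage_expressed = expression.expressed_flags(
            cage_filtered, config.expression_min_count
        ).reindex([l.locus_id for l in loci], fill_value=False)
        out[sp] = {
            "promoter": prom,
            "counts": counts,
            "library_sizes": libsize,
            "rpkm": rpkms,
            "rnaseq_expressed": rnaseq_expressed,
            "cage_tpm": cage_tpm,
            "cage_expressed": cage_expressed,
            "tmm_factors": factors,
        }
    return out


def evidence_stage(
    ds: SimulatedDataset,
    expr: Mapping[str, Mapping[str, Any]],
    polya: Mapping[str, pd.DataFrame],
    depth_labels: Mapping[str, Mapping[str, str]],
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    records: dict[str, pd.DataFrame] = {}
    for sp in ds.species:
        loci = ds.loci[sp]
        ann = pd.DataFrame(
            {
                "family": [l.family for l in loci],
                "length": [len(l.interval) for l in loci],
            },
            index=pd.Index([l.locus_id for l in loci], name="locus_id"),
        )
        cm = pd.Series({h.locus_id: h.cm_score for h in ds.cm_hits[sp]})
        loads = divergence.snp_density(loci, ds.variants[sp])
        nvar = pd.Series({ld.locus_id: ld.n_variants for ld in loads})
        depth = pd.Series(depth_labels[sp])
        records[sp] = evidence.integrate_evidence(
            ann,
            promoter=expr[sp]["promoter"],
            rnaseq_expressed=expr[sp]["rnaseq_expressed"],
            cage_expressed=expr[sp]["cage_expressed"],
            polya=polya[sp],
            cm_scores=cm,
            depth_labels=depth,
            variant_loads=nvar,
        )
    return records


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full simulated pipeline; write the report directory.

    Returns a summary dict (also written as report.json).  Deterministic
    for a fixed config: rerunning yields byte-identical outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - stage name is the contract
            raise StageError(name, exc) from exc

    ds = stage("simulate", simulate_stage, config)
    stage("emit", emit_dataset, ds, out / "inputs")
    groups = stage("synteny", synteny_stage, ds, config)
    matrix, recs, depth_labels = stage("dollo", dollo_stage, ds, groups, config)
    polya = stage("signatures", signatures_stage, ds, config)
    expr = stage("expression", expression_stage, ds, config)
    records = stage("evidence", evidence_stage, ds, expr, polya, depth_labels, config)

    synteny.write_groups_tsv(out / "groups.tsv", groups)
    matrix.to_csv(out / "presence_absence.tsv", sep="\t")
    dollo.write_reconstructions_tsv(out / "dollo.tsv", list(recs.values()))

    summary: dict[str, Any] = {"config": config.to_dict(), "species": {}}
    for sp in ds.species:
        rec = records[sp]
        rec.to_csv(out / f"evidence_{sp}.tsv", sep="\t")
        prom_table = evidence.summarize_promoter_table(rec)
        prom_table.to_csv(out / f"promoter_table_{sp}.tsv", sep="\t")
        support = evidence.summarize_support_categories(rec)
        support.to_csv(out / f"support_{sp}.tsv", sep="\t")
        ks_results = {}
        for family in ds.params.families:
            try:
                ks = evidence.compare_cm_by_promoter(rec, family, method=config.ks_method)
                ks_results[family] = {
                    "D": ks.D, "p_value": ks.p_value, "n1": ks.n1, "n2": ks.n2,
                }
            except (evidence.DataError, ValueError):
                ks_results[family] = None
        summary["species"][sp] = {
            "n_loci": int(len(rec)),
            "support_fractions": {
                fam: {b: float(row[b]) for b in evidence.SUPPORT_BINS}
                for fam, row in support.iterrows()
            },
            "ks_cm_by_promoter": ks_results,
        }

    digests = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.tsv"))
    }
    summary["digests"] = digests
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
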