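"""Multi-locus evaluation pipeline.

Runs every configured locus through the same stations — K2P distance
matrix, locus property summary, NJ tree with bootstrap supports, and one
barcoding-gap comparison per configured group pair — then ranks the loci
per comparison by differentiation power and writes a combined report
(rows: minimum between-group divergence, maximum intraspecific
divergence, discrimination verdict, rank; columns: loci).

A failure in any stage aborts that locus with a logged diagnostic while
the remaining loci proceed; the run log records the seed, package
version, skipped samples and bootstrap diagnostics so a rerun with the
same seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .distances import DistanceMatrix, distance_matrix
from .errors import BarcodeGapError, ConfigError
from .gap_analysis import (
    GroupComparison,
    GroupDef,
    LocusSummary,
    compare_groups,
    group_from_label,
    group_from_species,
    locus_summary,
    rank_loci,
)
from .njtree import BootstrapResult, Tree, bootstrap_support, nj, write_newick
from .seqio import (
    AlignedLocus,
    SampleMeta,
    check_alignment_metadata,
    metadata_index,
    read_alignment,
    read_sample_table,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationConfig:
    """Configuration of one multi-locus evaluation run.

    A comparison selector is either a group label from the metadata table
    or a comma-separated list of species names.
    """

    loci: tuple[tuple[str, str], ...]  # (locus name, alignment path)
    metadata_path: str
    comparisons: tuple[tuple[str, str], ...]  # (selector_a, selector_b)
    bootstrap_replicates: int = 1000
    seed: int = 0
    outdir: str | None = None
    support_threshold: float = 50.0

    def __post_init__(self) -> None:
        if not self.loci:
            raise ConfigError("at least one locus is required")
        if not self.comparisons:
            raise ConfigError("at least one comparison is required")
        names = [n for n, _ in self.loci]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate locus names")
        if self.bootstrap_replicates < 0:
            raise ConfigError("bootstrap_replicates must be >= 0")


def resolve_selector(
    meta: Sequence[SampleMeta] | Mapping[str, SampleMeta], selector: str
) -> GroupDef:
    """Resolve a group-label or species-list selector to a sample set."""
    index = meta if isinstance(meta, Mapping) else metadata_index(meta)
    labels = {m.group for m in index.values() if m.group}
    if selector in labels:
        return group_from_label(index, selector)
    species = tuple(s.strip() for s in selector.split(",") if s.strip())
    if not species:
        raise ConfigError(f"empty comparison selector {selector!r}")
    return group_from_species(index, species, label=selector)


@dataclass
class LocusResult:
    """Everything computed for one locus."""

    locus: AlignedLocus
    matrix: DistanceMatrix
    summary: LocusSummary
    tree: Tree | None
    bootstrap: BootstrapResult | None
    comparisons: list[GroupComparison]
    skipped_samples: list[str] = field(default_factory=list)


@dataclass
class PipelineReport:
    """Result bundle of one evaluation run."""

    results: dict[str, LocusResult]
    failures: dict[str, str]
    rankings: dict[str, list[GroupComparison]]  # "A|B" -> ranked per locus
    run_log: dict

    @property
    def ok(self) -> bool:
        return not self.failures


def _locus_seed(base_seed: int, locus_index: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, locus_index]).generate_state(1)[0]
        % (2**31)
    )


def _evaluate_locus(
    name: str,
    locus: AlignedLocus,
    meta: Mapping[str, SampleMeta],
    comparisons: Sequence[tuple[str, str]],
    replicates: int,
    seed: int,
) -> LocusResult:
    check_alignment_metadata(locus, meta)
    present = set(locus.sample_ids)
    skipped = sorted(sid for sid in meta if sid not in present)
    if skipped:
        logger.warning("locus %s: samples without sequence, skipped: %s", name, skipped)

    matrix = distance_matrix(locus)
    summary = locus_summary(locus, meta)

    tree = bootstrap = None
    if matrix.n >= 3:
        tree = nj(matrix)
        if replicates > 0:
            bootstrap = bootstrap_support(locus, tree, replicates, seed)
    else:
        logger.warning("locus %s: fewer than 3 samples, no tree built", name)

    comps = []
    for sel_a, sel_b in comparisons:
        ga = resolve_selector(meta, sel_a)
        gb = resolve_selector(meta, sel_b)
        comps.append(compare_groups(matrix, meta, ga, gb, name))
    return LocusResult(locus, matrix, summary, tree, bootstrap, comps, skipped)


def evaluate(config: EvaluationConfig) -> PipelineReport:
    """Run the full evaluation; see the module docstring."""
    meta = metadata_index(read_sample_table(config.metadata_path))
    # validate selectors before any heavy computation
    for sel_a, sel_b in config.comparisons:
        ga = resolve_selector(meta, sel_a)
        gb = resolve_selector(meta, sel_b)
        overlap = set(ga.sample_ids) & set(gb.sample_ids)
        if overlap:
            raise ConfigError(
                f"comparison {sel_a!r} vs {sel_b!r}: overlapping samples {sorted(overlap)}"
            )

    results: dict[str, LocusResult] = {}
    failures: dict[str, str] = {}
    for idx, (name, path) in enumerate(config.loci):
        try:
            locus = read_alignment(path, name)
            results[name] = _evaluate_locus(
                name,
                locus,
                meta,
                config.comparisons,
                config.bootstrap_replicates,
                _locus_seed(config.seed, idx),
            )
        except BarcodeGapError as exc:
            logger.error("locus %s aborted: %s", name, exc)
            failures[name] = str(exc)

    rankings: dict[str, list[GroupComparison]] = {}
    for c_idx, (sel_a, sel_b) in enumerate(config.comparisons):
        per_locus = [
            results[name].comparisons[c_idx]
            for name, _ in config.loci
            if name in results
        ]
        key = f"{sel_a}|{sel_b}"
        if len(per_locus) >= 2:
            ranked = rank_loci(per_locus)
            rankings[key] = ranked
            for comp, (name, _) in zip(
                ranked, (lp for lp in config.loci if lp[0] in results)
            ):
                # write the rank back onto the locus result
                results[name].comparisons[c_idx] = comp
        else:
            rankings[key] = per_locus

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "bootstrap_replicates": config.bootstrap_replicates,
        "loci": [name for name, _ in config.loci],
        "failed_loci": failures,
        "skipped_samples": {
            name: res.skipped_samples for name, res in results.items()
        },
        "bootstrap_diagnostics": {
            name: {
                "replicates_used": res.bootstrap.replicates_used,
                "replicates_failed": res.bootstrap.replicates_failed,
                "seed": res.bootstrap.seed,
            }
            for name, res in results.items()
            if res.bootstrap is not None
        },
    }
    report = PipelineReport(results, failures, rankings, run_log)
    if config.outdir is not None:
        write_report_bundle(report, config)
    return report


def _comparison_rows(
    loci: Sequence[str], ranked: Sequence[GroupComparison]
) -> list[list[str]]:
    by_locus = {c.locus_name: c for c in ranked}
    rows = []
    for metric, fmt in (
        ("min_between_group", lambda c: f"{c.min_interspecific:.4f}"),
        ("max_intraspecific", lambda c: f"{c.max_intraspecific:.4f}"),
        ("discriminates", lambda c: "yes" if c.success else "no"),
        ("rank", lambda c: "" if c.rank is None else str(c.rank)),
    ):
        rows.append(
            [metric]
            + [fmt(by_locus[l]) if l in by_locus else "NA" for l in loci]
        )
    return rows


def write_report_bundle(report: PipelineReport, config: EvaluationConfig) -> None:
    """Write per-locus artefacts and the combined comparison table."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for name, res in report.results.items():
        res.matrix.to_long_tsv(outdir / f"{name}.distances.tsv")
        res.matrix.to_phylip(outdir / f"{name}.distances.phylip")
        with open(outdir / f"{name}.summary.tsv", "w") as fh:
            fh.write("species\tavg_ungapped_length\tgc_percent\n")
            for sp in sorted(res.summary.avg_length):
                fh.write(
                    f"{sp}\t{res.summary.avg_length[sp]:.1f}\t"
                    f"{res.summary.gc_percent[sp]:.1f}\n"
                )
        with open(outdir / f"{name}.diagnostic_sites.tsv", "w") as fh:
            fh.write("locus\tcolumn\tgroup\tstate\n")
            for site in res.summary.diagnostic:
                for grp in sorted(site.states):
                    fh.write(f"{name}\t{site.column}\t{grp}\t{site.states[grp]}\n")
        if res.tree is not None:
            write_newick(
                res.tree,
                outdir / f"{name}.nj.nwk",
                support_threshold=config.support_threshold,
            )

    locus_names = [n for n, _ in config.loci if n in report.results]
    with open(outdir / "comparison_report.tsv", "w") as fh:
        fh.write("comparison\tmetric\t" + "\t".join(locus_names) + "\n")
        for key, ranked in report.rankings.items():
            for row in _comparison_rows(locus_names, ranked):
                fh.write(key + "\t" + "\t".join(row) + "\n")

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(report.run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config_file(path: str | Path) -> EvaluationConfig:
    """Read a flat INI-style evaluation config.

    Sections: ``[loci]`` (name = alignment path), ``[comparisons]``
    (any key = ``selectorA : selectorB``), ``[run]`` (metadata,
    replicates, seed, outdir, support_threshold).
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ConfigError(f"cannot read config file {path}")
    if "loci" not in parser or "comparisons" not in parser or "run" not in parser:
        raise ConfigError("config needs [loci], [comparisons] and [run] sections")
    loci = tuple(parser["loci"].items())
    comparisons = []
    for _, value in parser["comparisons"].items():
        if ":" not in value:
            raise ConfigError(f"comparison {value!r} must be 'selectorA : selectorB'")
        a, b = value.split(":", 1)
        comparisons.append((a.strip(), b.strip()))
    run = parser["run"]
    if "metadata" not in run:
        raise ConfigError("[run] section needs a metadata path")
    return EvaluationConfig(
        loci=loci,
        metadata_path=run["metadata"],
        comparisons=tuple(comparisons),
        bootstrap_replicates=run.getint("replicates", 1000),
        seed=run.getint("seed", 0),
        outdir=run.get("outdir"),
        support_threshold=run.getfloat("support_threshold", 50.0),
    )
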