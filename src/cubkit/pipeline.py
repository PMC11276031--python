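"""End-to-end orchestration: filter -> metrics -> plots -> optimal codons
-> cross-species comparison, driven by one YAML config.

Every stage writes plain-text TSV intermediates so runs are diffable; a
machine-readable ``summary.json`` collects the headline numbers (kept
gene counts, neutrality slopes, CoA inertias, optimal-codon sets,
comparison verdicts).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon_metrics import (
    correlation_matrix,
    count_codons,
    metrics_table,
    pool_counts,
    rscu,
    rscu_series,
)
from .genetics import GENETIC_CODE, SCHEMES, SYNONYMOUS_CODONS, FamilyScheme
from .optimal_codon_screen import (
    ending_tally,
    expression_groups,
    high_frequency_codons,
    optimal_codons,
    shared_codons,
)
from .plots import coa_plot, enc_plot, neutrality_plot, pr2_plot
from .selection_inference import (
    correspondence_analysis,
    enc_ratio_histogram,
    gc_class_labels,
    neutrality_fit,
    pr2_point,
)
from .sequence_io import filter_cds, parse_fasta, write_fasta, write_filter_report
from .species_comparison import parse_kazusa, table_from_counts, usage_ratio

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("cubkit")

_KNOWN_KEYS = {
    "inputs", "outdir", "scheme", "fraction", "delta_rscu", "min_len",
    "comparison_tables", "seed", "log_level", "literal_groups",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    inputs: dict[str, Path]              # species label -> CDS FASTA
    outdir: Path
    scheme: str = "split"
    fraction: float = 0.10
    delta_rscu: float = 0.08
    min_len: int = 300
    comparison_tables: dict[str, Path] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    literal_groups: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "inputs" not in raw or not raw["inputs"]:
            raise ValueError("config needs at least one entry under 'inputs'")
        cfg = cls(
            inputs={k: Path(v) for k, v in raw["inputs"].items()},
            outdir=Path(raw.get("outdir", "cubkit_out")),
            scheme=raw.get("scheme", "split"),
            fraction=float(raw.get("fraction", 0.10)),
            delta_rscu=float(raw.get("delta_rscu", 0.08)),
            min_len=int(raw.get("min_len", 300)),
            comparison_tables={
                k: Path(v) for k, v in (raw.get("comparison_tables") or {}).items()
            },
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            literal_groups=bool(raw.get("literal_groups", False)),
        )
        if cfg.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {cfg.scheme!r}")
        for label, p in {**cfg.inputs, **cfg.comparison_tables}.items():
            if not p.exists():
                raise FileNotFoundError(f"{label}: {p} does not exist")
        return cfg


def _rscu_table_frame(pooled, scheme: FamilyScheme) -> pd.DataFrame:
    vals = rscu(pooled, scheme)
    rows = [
        {
            "amino_acid": GENETIC_CODE[c],
            "codon": c,
            "count": pooled[c],
            "rscu": vals[c],
        }
        for c in sorted(vals, key=lambda c: (GENETIC_CODE[c], c))
    ]
    return pd.DataFrame(rows)


def _analyse_species(
    label: str, fasta: Path, outdir: Path, cfg: RunConfig
) -> dict:
    scheme = SCHEMES[cfg.scheme]
    sp_dir = outdir / label
    sp_dir.mkdir(parents=True, exist_ok=True)

    records = parse_fasta(fasta)
    report = filter_cds(records, min_len=cfg.min_len)
    write_fasta(report.kept, sp_dir / "filtered.fasta")
    write_filter_report(report, sp_dir / "filter_report.tsv")
    logger.info("%s: %d/%d CDS kept", label, len(report.kept), report.n_input)
    if len(report.kept) < 3:
        raise RuntimeError(f"{label}: fewer than 3 CDS pass the screen")

    genes = report.kept
    tables = [count_codons(g) for g in genes]
    pooled = pool_counts(tables)

    metrics = metrics_table(genes)
    metrics.to_csv(sp_dir / "gene_metrics.tsv", sep="\t")
    metrics.mean(numeric_only=True).to_csv(
        sp_dir / "genome_means.tsv", sep="\t", header=["mean"]
    )
    corr = correlation_matrix(metrics)
    corr.to_csv(sp_dir / "index_correlations.tsv", sep="\t")

    rscu_frame = _rscu_table_frame(pooled, scheme)
    rscu_frame.to_csv(sp_dir / "rscu_pooled.tsv", sep="\t", index=False)
    pooled_rscu = rscu(pooled, scheme)
    hi_freq = high_frequency_codons(pooled_rscu)

    hist = enc_ratio_histogram(metrics["enc"], metrics["gc3s"])
    hist.to_frame().to_csv(sp_dir / "enc_ratio_histogram.tsv", sep="\t", index=False)
    enc_plot(metrics["gc3s"], metrics["enc"], sp_dir / "enc_plot.png", label)

    pr2 = pd.DataFrame(
        [pr2_point(t) for t in tables], index=metrics.index, columns=["x", "y"]
    )
    pr2.to_csv(sp_dir / "pr2_points.tsv", sep="\t")
    pr2_plot(pr2["x"], pr2["y"], sp_dir / "pr2_plot.png", label)

    fit = neutrality_fit(metrics["gc3"], metrics["gc12"])
    neutrality_plot(metrics["gc3"], metrics["gc12"], fit,
                    sp_dir / "neutrality_plot.png", label)

    rscu_matrix = pd.DataFrame(
        [rscu_series(t, scheme) for t in tables], index=metrics.index
    )[list(SYNONYMOUS_CODONS)]
    coa = correspondence_analysis(rscu_matrix)
    coa.row_coords.to_csv(sp_dir / "coa_gene_coords.tsv", sep="\t")
    coa.col_coords.to_csv(sp_dir / "coa_codon_coords.tsv", sep="\t")
    labels = gc_class_labels(metrics.loc[coa.row_coords.index, "gc_all"])
    coa_plot(coa, labels, sp_dir / "coa_plot.png", label)

    groups = expression_groups(
        metrics["enc"].to_dict(),
        fraction=cfg.fraction,
        low_enc_is_high_expression=not cfg.literal_groups,
    )
    by_id = {g.id: t for g, t in zip(genes, tables)}
    high_counts = pool_counts(by_id[i] for i in groups.high)
    low_counts = pool_counts(by_id[i] for i in groups.low)
    screen = optimal_codons(
        high_counts, low_counts, pooled_rscu,
        threshold=cfg.delta_rscu, scheme=scheme,
    )
    screen.to_csv(sp_dir / "optimal_codons.tsv", sep="\t")
    optimal = sorted(screen.index[screen["optimal"]])

    return {
        "label": label,
        "n_input": report.n_input,
        "n_kept": len(report.kept),
        "rejection_counts": dict(report.counts),
        "mean_enc": float(metrics["enc"].mean()),
        "mean_gc_all": float(metrics["gc_all"].mean()),
        "neutrality": {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "pearson_r": fit.pearson_r,
            "p_value": fit.p_value,
            "mutation_share_pct": fit.mutation_share,
            "selection_share_pct": fit.selection_share,
            "negative_slope": fit.slope < 0,
        },
        "coa_axis_inertia_pct": [round(v, 4) for v in coa.inertia_percent[:4]],
        "high_frequency_codons": sorted(hi_freq),
        "optimal_codons": optimal,
        "_pooled": pooled,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every species and write the report bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    Any stage failure raises with the species label and stage attached.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())

    summary: dict = {
        "cubkit_version": __version__,
        "parameters": {
            "scheme": config.scheme,
            "fraction": config.fraction,
            "delta_rscu": config.delta_rscu,
            "min_len": config.min_len,
            "seed": config.seed,
        },
        "species": {},
        "comparisons": {},
    }
    try:
        results = {}
        for label, fasta in sorted(config.inputs.items()):
            try:
                results[label] = _analyse_species(label, fasta, outdir, config)
            except Exception as exc:
                raise RuntimeError(f"species stage failed for {label}: {exc}") from exc

        labels = sorted(results)
        for label in labels:
            info = dict(results[label])
            info.pop("_pooled")
            summary["species"][label] = info

        if len(labels) >= 2:
            hi_sets = [set(results[l]["high_frequency_codons"]) for l in labels]
            shared = shared_codons(hi_sets)
            summary["comparisons"]["shared_high_frequency"] = {
                "species": labels,
                "codons": sorted(shared),
                "tally": ending_tally(shared) if shared else
                         {"AU_ending": 0, "CG_ending": 0},
            }

        freq_tables = {
            l: table_from_counts(results[l]["_pooled"], species=l) for l in labels
        }
        for label, path in sorted(config.comparison_tables.items()):
            freq_tables[label] = parse_kazusa(path.read_text(), species=label)
        names = sorted(freq_tables)
        ratio_rows = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                rep = usage_ratio(freq_tables[a], freq_tables[b])
                rep.table.to_csv(outdir / f"ratio_{a}_vs_{b}.tsv", sep="\t")
                ratio_rows.append(
                    {"a": a, "b": b, "n_flagged": rep.n_flagged,
                     "verdict": rep.verdict}
                )
        summary["comparisons"]["usage_ratios"] = ratio_rows

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %s", outdir)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
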