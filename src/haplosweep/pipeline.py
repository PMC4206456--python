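"""End-to-end orchestration: scan -> collapse -> HSI -> evaluation -> F_ST.

Every stage writes plain TSV/BED so it can also be run standalone, and a
run manifest (config hash, seed, package versions, stage counts) makes a
run reproducible: identical config and inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__, catalog_eval, haploscan, io_formats, similarity
from .types import ConfigurationError, HaplosweepError, SelectionSignal

logger = logging.getLogger("haplosweep")


@dataclass
class PipelineConfig:
    """Inputs and knobs for one full run.

    ``panel_paths`` maps population label to one or more phased panel
    files (VCF or ``.hap``/``.legend``); ``map_paths`` maps chromosome
    label to a genetic-map file covering it.
    """

    panel_paths: dict[str, list[str]]
    map_paths: dict[str, str]
    catalog_path: str
    outgroup_path: str
    out_dir: str
    east_asian_labels: tuple[str, ...] = ("CHB", "CHD", "CHS", "JPT")
    grid_min: float = 0.05
    grid_max: float = 0.95
    grid_step: float = 0.05
    skip_allowance: int = 0
    majority_threshold: float = 0.9
    fst_pairs: tuple[tuple[str, str], ...] = ()
    panel_format: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.panel_paths:
            raise ConfigurationError("no panels configured")
        for pair in self.fst_pairs:
            for pop in pair:
                if pop not in self.panel_paths:
                    raise ConfigurationError(
                        f"F_ST pair {pair[0]}-{pair[1]} names population "
                        f"{pop!r} with no configured panel"
                    )
        paths = [p for ps in self.panel_paths.values() for p in ps]
        if len(paths) != len(set(paths)):
            raise ConfigurationError("panel paths must be distinct")

    @property
    def grid(self) -> tuple[float, ...]:
        bins = []
        f = self.grid_min
        while f <= self.grid_max + 1e-9:
            bins.append(round(f, 6))
            f += self.grid_step
        return tuple(bins)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "fst_pairs" in d:
            d["fst_pairs"] = tuple(
                tuple(p.split("-")) if isinstance(p, str) else tuple(p)
                for p in d["fst_pairs"]
            )
        if "east_asian_labels" in d:
            d["east_asian_labels"] = tuple(d["east_asian_labels"])
        return PipelineConfig(**d)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _stage(name: str):
    """Wrap a stage so failures name the stage that died."""

    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except HaplosweepError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc

        return wrapped

    return deco


@_stage("load")
def _load_inputs(config: PipelineConfig):
    catalog = io_formats.read_gwas_catalog(config.catalog_path)
    outgroup = io_formats.read_outgroup_table(config.outgroup_path)
    maps = {
        chrom: io_formats.read_genetic_map(path, chrom)
        for chrom, path in config.map_paths.items()
    }
    panels: dict[str, list] = {}
    for pop, paths in config.panel_paths.items():
        panels[pop] = []
        for path in paths:
            panel = io_formats.read_phased_panel(
                path, config.panel_format, population=pop
            )
            chroms = {s.chromosome for s in panel.snps}
            for chrom in chroms:
                if chrom not in maps:
                    raise ConfigurationError(
                        f"no genetic map for chromosome {chrom} "
                        f"(panel {path})"
                    )
            if len(chroms) == 1:
                panel = io_formats.attach_genetic_map(
                    panel, maps[chroms.pop()]
                )
            panels[pop].append(panel)
            logger.info(
                "loaded %s: %d chromosomes x %d SNPs",
                path,
                panel.n_chromosomes,
                panel.n_snps,
            )
    return catalog, outgroup, panels


@_stage("scan")
def _scan(config: PipelineConfig, panels) -> dict[str, list[SelectionSignal]]:
    final: dict[str, list[SelectionSignal]] = {}
    for pop, pop_panels in panels.items():
        signals: list[SelectionSignal] = []
        for panel in pop_panels:
            forms = haploscan.scan_population(
                panel, bins=config.grid, skip_allowance=config.skip_allowance
            )
            signals.extend(haploscan.score_signals(forms, pop))
        significant = [s for s in signals if s.significant]
        final[pop] = haploscan.collapse_to_highest_frequency(significant)
        logger.info(
            "%s: %d candidate signals, %d significant, %d after collapse",
            pop,
            len(signals),
            len(significant),
            len(final[pop]),
        )
    return final


@_stage("hsi")
def _hsi_table(final_signals: dict[str, list[SelectionSignal]]):
    """Pairwise HSI between overlapping final signals across populations."""
    rows = []
    flat = [s for sigs in final_signals.values() for s in sigs]
    for i, a in enumerate(flat):
        for b in flat[i + 1 :]:
            if a.population == b.population or not a.overlaps(b):
                continue
            r = similarity.hsi(a.form, b.form)
            rows.append(
                {
                    "chromosome": a.chromosome,
                    "population_a": a.population,
                    "start_a": a.start_bp,
                    "end_a": a.end_bp,
                    "population_b": b.population,
                    "start_b": b.start_bp,
                    "end_b": b.end_bp,
                    "hsi": r.value,
                    "shared_snps": r.shared_snp_count,
                    "classification": r.classification,
                }
            )
    return rows


def run_all(config: PipelineConfig) -> dict:
    """Execute the full four-step analysis and write the report bundle.

    Returns a summary dict (also written as ``manifest.json``).  Output
    files: ``signals_<pop>.tsv``, ``signals.bed``, ``hsi.tsv``,
    ``verdicts.tsv``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    catalog, outgroup, panels = _load_inputs(config)
    final_signals = _scan(config, panels)

    all_final: list[SelectionSignal] = []
    for pop in sorted(final_signals):
        io_formats.write_signals_tsv(
            final_signals[pop], out_dir / f"signals_{pop}.tsv"
        )
        all_final.extend(final_signals[pop])
    io_formats.write_signals_bed(all_final, out_dir / "signals.bed")

    hsi_rows = _hsi_table(final_signals)
    with open(out_dir / "hsi.tsv", "w") as fh:
        cols = [
            "chromosome",
            "population_a",
            "start_a",
            "end_a",
            "population_b",
            "start_b",
            "end_b",
            "hsi",
            "shared_snps",
            "classification",
        ]
        fh.write("\t".join(cols) + "\n")
        for row in hsi_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    verdicts = _evaluate(config, catalog, all_final, panels, outgroup)
    io_formats.write_report_tsv(verdicts, out_dir / "verdicts.tsv")

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": _versions(),
        "counts": {
            "catalog_rows": len(catalog),
            "final_signals": len(all_final),
            "hsi_pairs": len(hsi_rows),
            "verdicts": len(verdicts),
            "supports_thrifty": sum(v.supports_thrifty for v in verdicts),
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


@_stage("evaluate")
def _evaluate(config, catalog, signals, panels, outgroup):
    return catalog_eval.evaluate(
        catalog,
        signals,
        panels,
        outgroup,
        fst_pairs=config.fst_pairs,
        east_asian_labels=config.east_asian_labels,
        majority_threshold=config.majority_threshold,
    )


def _versions() -> dict:
    import numpy
    import pandas

    return {
        "haplosweep": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
    }
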