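"""End-to-end orchestration: trim -> scan -> demarcate -> shared-site tests ->
codon degeneration, from a single YAML config, with reproducible outputs.

Every stage consumes the previous stage's serialised outputs, all thresholds
default to the study-standard values (500 kb/100 kb divergence windows,
100 kb/20 kb GC windows, 100 kb -> 10 kb stepwise demarcation at a 1% cutoff)
and a run manifest records the config hash and seed so identical configs
reproduce byte-identical result bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .alignment import (
    GenomeAlignment,
    read_alignment,
    remove_gap_columns,
    write_alignment,
    write_column_map,
)
from .codons import (
    CodonSwitchTable,
    classify_codon_switches,
    degeneration_sign_tests,
    excess_and_frequency,
    extract_coding_alignment,
    load_preferred_table,
    read_genes_bed,
    switch_table_frame,
)
from .demarcation import (
    DemarcationConfig,
    RegionCall,
    call_introgression_tract,
    demarcate_elevated_region,
    region_calls_to_bed,
)
from .divergence import ScanConfig, gc_content_windows, sliding_divergence, windows_to_frame
from .shared_sites import SignTestResult, count_shared_patterns, shared_site_test
from .simulate import SimulationConfig, simulate_dataset, write_dataset

log = logging.getLogger("introscan")

DEFAULT_LINEAGES = {
    "L1": {"mat_A": "L1A", "mat_a": "L1a"},
    "L4": {"mat_A": "L4A", "mat_a": "L4a"},
    "L9": {"mat_A": "L9A", "mat_a": "L9a"},
}


class PipelineConfigError(ValueError):
    """Raised before any computation when the pipeline config is invalid."""


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None  # alignment: {chrom: path}, genes, codon_table
    outgroup: str = "NC"
    lineages: dict[str, dict[str, str]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LINEAGES.items()}
    )
    mat_chromosome: str = "LGI"
    scan: ScanConfig = field(default_factory=ScanConfig)
    gc_scan: ScanConfig = field(default_factory=lambda: ScanConfig(100_000, 20_000))
    demarcation: DemarcationConfig = field(
        default_factory=lambda: DemarcationConfig(introgression_margin=0.003)
    )
    tract_reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if (self.simulate is None) == (self.inputs is None):
            raise PipelineConfigError("exactly one of 'simulate' or 'inputs' required")
        seen: set[str] = {self.outgroup}
        for lineage, roles in self.lineages.items():
            if set(roles) != {"mat_A", "mat_a"}:
                raise PipelineConfigError(
                    f"lineage {lineage}: needs exactly mat_A and mat_a samples"
                )
            for s in roles.values():
                if s in seen:
                    raise PipelineConfigError(f"sample {s!r} assigned to multiple roles")
                seen.add(s)
        for lineage in self.lineages:
            self.tract_reference.setdefault(lineage, self.outgroup)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base_dir: Path | None = None) -> "PipelineConfig":
        raw = dict(raw)
        if "seed" not in raw:
            raise PipelineConfigError("config must set a seed")
        scan = ScanConfig(**raw.pop("scan", {})) if "scan" in raw else ScanConfig()
        gc = ScanConfig(**raw.pop("gc_scan", {})) if "gc_scan" in raw else ScanConfig(100_000, 20_000)
        dem_kwargs = raw.pop("demarcation", {"introgression_margin": 0.003})
        dem_kwargs.setdefault("introgression_margin", 0.003)
        dem = DemarcationConfig(**dem_kwargs)
        inputs = raw.get("inputs")
        if inputs and base_dir is not None:
            inputs = dict(inputs)
            inputs["alignment"] = {
                c: str(base_dir / p) for c, p in inputs["alignment"].items()
            }
            for key in ("genes", "codon_table"):
                if key in inputs:
                    inputs[key] = str(base_dir / inputs[key])
            raw["inputs"] = inputs
        return cls(scan=scan, gc_scan=gc, demarcation=dem, **raw)


@dataclass
class ResultBundle:
    """In-memory results of one pipeline run plus the paths written."""

    config: PipelineConfig
    paths: dict[str, Path]
    regions: dict[str, dict[str, RegionCall]]  # lineage -> label -> call
    shared: dict[str, tuple] = field(default_factory=dict)  # lineage -> (counts, test)
    switch_tables: dict[str, CodonSwitchTable] = field(default_factory=dict)
    codon_tests: dict[str, dict[str, SignTestResult]] = field(default_factory=dict)
    mat_length: int = 0


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)

    payload = dataclasses.asdict(cfg)
    payload.pop("output_dir", None)  # bundle content is location-independent
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _obtain_inputs(cfg: PipelineConfig):
    """Simulate or load the original-space alignment, genes and codon table."""
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs["seed"] = cfg.seed
        sim_cfg = _sim_config_from_dict(sim_kwargs)
        ds = simulate_dataset(sim_cfg)
        data_dir = cfg.output_dir / "data"
        write_dataset(ds, data_dir)
        return ds.alignment, ds.genes, ds.codon_table, ds.truth
    inputs = cfg.inputs or {}
    if "alignment" not in inputs:
        raise PipelineConfigError("inputs must provide per-chromosome alignment paths")
    for _, p in inputs["alignment"].items():
        if not Path(p).exists():
            raise PipelineConfigError(f"missing input file {p}")
    aln = read_alignment(inputs["alignment"])
    genes = read_genes_bed(inputs["genes"]) if "genes" in inputs else []
    table = load_preferred_table(inputs["codon_table"]) if "codon_table" in inputs else None
    return aln, genes, table, None


def _sim_config_from_dict(kwargs: dict[str, Any]) -> SimulationConfig:
    from .simulate import Centromere, LineageTree, SwitchRates

    kwargs = dict(kwargs)
    for key, klass in (
        ("lineage_tree", LineageTree),
        ("centromere", Centromere),
        ("switch_rates", SwitchRates),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = klass(**kwargs[key])
    for key in ("central_region", "tract"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)


def run_pipeline(cfg: PipelineConfig) -> ResultBundle:
    """Run all stages and write the result bundle under ``cfg.output_dir``."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log.info("obtaining inputs (seed=%d)", cfg.seed)
    original, genes, table, truth = _obtain_inputs(cfg)
    _check_roles(cfg, original)

    log.info("trimming gap columns")
    trimmed, cmap = remove_gap_columns(original)
    trimmed_dir = out / "trimmed"
    paths = {"trimmed": trimmed_dir}
    write_alignment(trimmed, trimmed_dir)
    write_column_map(cmap, out / "column_map.json")
    paths["column_map"] = out / "column_map.json"

    log.info("window scans")
    mat = cfg.mat_chromosome
    pairs = []
    for lineage, roles in cfg.lineages.items():
        pairs.append((roles["mat_A"], roles["mat_a"]))
        ref = cfg.tract_reference[lineage]
        pairs.append((roles["mat_a"], ref))
        pairs.append((roles["mat_A"], ref))
    windows = []
    for chrom in trimmed.chromosome_names:
        for x, y in dict.fromkeys(pairs):
            windows.extend(sliding_divergence(trimmed, chrom, x, y, cfg.scan))
    _write_tsv(windows_to_frame(windows), out / "divergence_windows.tsv")
    paths["divergence_windows"] = out / "divergence_windows.tsv"
    gc_samples = [cfg.outgroup, next(iter(cfg.lineages.values()))["mat_A"]]
    gc_windows = []
    for chrom in trimmed.chromosome_names:
        for s in gc_samples:
            gc_windows.extend(gc_content_windows(trimmed, chrom, s, cfg.gc_scan))
    _write_tsv(windows_to_frame(gc_windows), out / "gc_windows.tsv")
    paths["gc_windows"] = out / "gc_windows.tsv"

    log.info("demarcation and tract calls")
    regions: dict[str, dict[str, RegionCall]] = {}
    rows = []
    for lineage, roles in cfg.lineages.items():
        pa1, central, pa2 = demarcate_elevated_region(
            trimmed, mat, roles["mat_A"], roles["mat_a"], cfg.demarcation
        )
        calls = {"PA1": pa1, "central": central, "PA2": pa2}
        if not central.empty:
            calls["tract"] = call_introgression_tract(
                trimmed, mat, roles["mat_a"], roles["mat_A"],
                cfg.tract_reference[lineage], central, cfg.demarcation,
            )
        regions[lineage] = calls
        for label, call in calls.items():
            rows.append(
                {
                    "lineage": lineage,
                    "label": label,
                    "chromosome": call.chromosome,
                    "start": call.start,
                    "end": call.end,
                    "length": call.length,
                    "mean_divergence": call.evidence.get(
                        "mean_divergence", call.evidence.get("mean_query_divergence", float("nan"))
                    ),
                    "flags": ";".join(call.flags),
                }
            )
    _write_tsv(pd.DataFrame(rows), out / "regions.tsv")
    paths["regions"] = out / "regions.tsv"
    all_calls = [c for calls in regions.values() for c in calls.values() if not c.empty]
    (out / "regions.bed").write_text(region_calls_to_bed(all_calls))
    paths["regions_bed"] = out / "regions.bed"

    log.info("shared-site tests")
    shared: dict[str, tuple] = {}
    srows = []
    for lineage, roles in cfg.lineages.items():
        central = regions[lineage]["central"]
        if central.empty:
            continue
        counts = count_shared_patterns(
            trimmed, roles["mat_a"], roles["mat_A"], cfg.tract_reference[lineage],
            mat, (central.start, central.end),
        )
        test = shared_site_test(counts)
        shared[lineage] = (counts, test)
        srows.append(
            {
                "lineage": lineage,
                "X": counts.triple[0],
                "Y": counts.triple[1],
                "Z": counts.triple[2],
                "start": counts.start,
                "end": counts.end,
                "n_XZ": counts.n_xz,
                "n_YZ": counts.n_yz,
                "identity_XZ": counts.identity_xz,
                "identity_YZ": counts.identity_yz,
                "k": test.k,
                "n": test.n,
                "p_value": test.p_value,
            }
        )
    _write_tsv(pd.DataFrame(srows), out / "shared_sites.tsv")
    paths["shared_sites"] = out / "shared_sites.tsv"

    log.info("codon degeneration")
    switch_tables: dict[str, CodonSwitchTable] = {}
    codon_tests: dict[str, dict[str, SignTestResult]] = {}
    region_i = _common_tract(regions, mat, trimmed)
    if genes and table is not None and region_i is not None:
        for lineage, roles in cfg.lineages.items():
            coding = extract_coding_alignment(trimmed, genes, region_i)
            tbl = classify_codon_switches(
                coding.codons[cfg.outgroup],
                coding.codons[roles["mat_a"]],
                coding.codons[roles["mat_A"]],
                table,
            )
            excess_and_frequency(tbl)
            switch_tables[lineage] = tbl
            codon_tests[lineage] = degeneration_sign_tests(tbl)
        _write_tsv(switch_table_frame(switch_tables), out / "codon_switches.tsv")
        paths["codon_switches"] = out / "codon_switches.tsv"
        with open(out / "codon_tests.json", "w") as fh:
            json.dump(_codon_tests_payload(switch_tables, codon_tests), fh,
                      indent=1, sort_keys=True)
        paths["codon_tests"] = out / "codon_tests.json"

    manifest = {
        "package": "introscan",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": _config_hash(cfg),
        "stages": sorted(str(k) for k in paths),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = out / "manifest.json"

    bundle = ResultBundle(
        cfg, paths, regions, shared, switch_tables, codon_tests,
        mat_length=trimmed.length(mat),
    )
    (out / "summary.md").write_text(summarize_report(bundle))
    paths["summary"] = out / "summary.md"
    return bundle


def _check_roles(cfg: PipelineConfig, aln: GenomeAlignment) -> None:
    needed = {cfg.outgroup}
    for lineage, roles in cfg.lineages.items():
        needed.update(roles.values())
        needed.add(cfg.tract_reference[lineage])
    missing = sorted(needed - set(aln.sample_ids))
    if missing:
        raise PipelineConfigError(f"samples missing from alignment: {missing}")


def _common_tract(regions, mat: str, trimmed) -> tuple[str, int, int] | None:
    """Intersection of the called tracts across lineages (the region
    introgressed in every lineage), used for the codon analysis."""
    tracts = [
        calls["tract"] for calls in regions.values()
        if "tract" in calls and not calls["tract"].empty
    ]
    if not tracts:
        return None
    start = max(t.start for t in tracts)
    end = min(t.end for t in tracts)
    if end <= start:
        return None
    return (mat, start, end)


def _codon_tests_payload(tables, tests) -> dict:
    payload: dict[str, Any] = {}
    for lineage, tbl in tables.items():
        payload[lineage] = {
            "counts": {
                "pr_to_npr": tbl.n_pr_to_npr,
                "npr_to_pr": tbl.n_npr_to_pr,
                "excess": tbl.excess,
                "frequency_per_1000": tbl.frequency,
            },
            "bookkeeping": {
                "total_codons": tbl.total_codons,
                "n_analyzed": tbl.n_analyzed,
                "n_excluded_missing": tbl.n_excluded_missing,
                "n_excluded_nonsyn": tbl.n_excluded_nonsyn,
                "n_uninformative": tbl.n_uninformative,
            },
            "tests": {
                name: {"k": t.k, "n": t.n, "p_value": t.p_value, "defined": t.defined}
                for name, t in tests[lineage].items()
            },
        }
    return payload


def summarize_report(bundle: ResultBundle) -> str:
    """One-page markdown summary of a result bundle."""
    lines = ["# introscan run summary", ""]
    mat = bundle.config.mat_chromosome
    lines.append(f"Mat chromosome: {mat} ({bundle.mat_length:,} bp trimmed)")
    lines.append("")
    lines.append("## Regions")
    for lineage, calls in bundle.regions.items():
        lines.append(f"### {lineage}")
        for label in ("PA1", "central", "PA2", "tract"):
            call = calls.get(label)
            if call is None or (label == "tract" and call.empty):
                if label == "tract":
                    lines.append("- tract: no tract called")
                continue
            frac = ""
            if label == "tract" and bundle.mat_length:
                frac = f" ({100.0 * call.length / bundle.mat_length:.1f}% of chromosome)"
            mean = call.evidence.get(
                "mean_divergence", call.evidence.get("mean_query_divergence")
            )
            mean_s = (
                f", mean divergence {mean:.4f}"
                if isinstance(mean, float) and mean == mean
                else ""
            )
            lines.append(
                f"- {label}: [{call.start:,}, {call.end:,}) = {call.length:,} bp{frac}{mean_s}"
            )
    if bundle.shared:
        lines.append("")
        lines.append("## Shared-nucleotide tests (central region)")
        for lineage, (counts, test) in bundle.shared.items():
            lines.append(
                f"- {lineage}: {counts.triple[0]}={counts.triple[2]} at {counts.n_xz:,} "
                f"sites vs {counts.triple[1]}={counts.triple[2]} at {counts.n_yz:,}; "
                f"p = {test.p_value:.3g}"
            )
    if bundle.switch_tables:
        lines.append("")
        lines.append("## Codon degeneration (common tract)")
        for lineage, tbl in bundle.switch_tables.items():
            for allele in ("mat_a", "mat_A"):
                lines.append(
                    f"- {lineage} {allele}: {tbl.n_pr_to_npr[allele]} PR->NPR vs "
                    f"{tbl.n_npr_to_pr[allele]} NPR->PR, excess {tbl.excess[allele]}, "
                    f"F = {tbl.frequency[allele]:.2f} per 1000 codons"
                )
    lines.append("")
    return "\n".join(lines)


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
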