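"""Config-driven pipeline stages: simulate, call, analyze, power.

Each stage is a plain function over a config dict (loaded from YAML) and an
output directory, so the CLI stays a thin shell and library users can drive
the same stages from Python. Every CSV artifact starts with a provenance
comment (tool version, config hash, seed); nothing written depends on wall
time, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import DataQualityError, ValidationError
from .haplotyping import (call_haplotype, call_tpi, discover_snps,
                          select_marker_sites, tpi_allele_frequency)
from .io import builtin_references, load_reference, read_specimens
from .popstats import (CONTRAST_HAPLOTYPE, FOCAL_HAPLOTYPE, RegionScheme,
                       calls_to_frame, chi_square_uniform, frequency_table,
                       m_results, one_way_anova, regional_compare,
                       tukey_hsd, two_sample_t)
from .simulate import (MigrationScenario, SourcePopulation, WrightFisher,
                       run_power_analysis, synthesize_study)

DEFAULT_CONFIG = {
    "seed": 0,
    "snp_threshold": 0.10,
    "tpi_mode": "half_weight",
    "test_variant": "pooled",
    "delimiter": "|",
    "paths": {},        # specimens/metadata/references overrides
    "simulate": {
        "phased_males": False,
        "segments": ["sCOIB", "sTpiE", "sTpi140"],
        "south": {"n_destinations": 8, "n_sampled": 30},
        "north": {"n_founders": 5, "n_destinations": 8, "n_sampled": 30},
    },
    "call": {"segments": ["sCOIB"]},
    "analyze": {"grouping": "state_year",
                "schemes": ["east_west", "north_south"],
                "pies": False},
    "power": {"founder_sizes": [5, 50, 500], "replicates": 200,
              "n_collections_per_side": 10, "n_sampled": 30, "alpha": 0.05},
}

_SCHEMES = {"east_west": RegionScheme.east_west,
            "north_south": RegionScheme.north_south}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, {k: v for k, v in overrides.items()
                                if v is not None})
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: dict) -> str:
    return f"# haplomig {__version__} config={config_hash(cfg)} seed={cfg['seed']}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, index=False)


def load_references(cfg: dict) -> dict:
    refs = builtin_references()
    for name, spec in (cfg.get("paths", {}).get("references") or {}).items():
        refs[name] = load_reference(spec["path"], int(spec["offset"]),
                                    spec.get("frame", name), name=name)
    return refs


def _scenario(block: dict, seed: int, base_source: dict | None = None) -> MigrationScenario:
    block = dict(block or {})
    src_block = dict(base_source or {})
    src_block.update(block.pop("source", {}) or {})
    if "coib_freqs" in src_block:
        src_block["coib_freqs"] = dict(src_block["coib_freqs"])
    if "stpie_sites" in src_block:
        src_block["stpie_sites"] = tuple(
            tuple(s) for s in src_block["stpie_sites"])
    source = SourcePopulation(**src_block)
    wf = block.pop("wright_fisher", None)
    expansion = WrightFisher(int(wf["gens"]), int(wf["N"])) if wf else None
    if "states" in block:
        block["states"] = tuple(block["states"])
    return MigrationScenario(source=source, expansion=expansion,
                             seed=block.pop("seed", seed), **block)


# ---------------------------------------------------------------------------

def run_simulate(cfg: dict, outdir, force: bool = False) -> Path:
    """Synthesize the two-region study fixture under ``outdir/simulate``."""
    out = Path(outdir) / "simulate"
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"{out} exists; pass --force to overwrite")
    sim = cfg["simulate"]
    seed = int(cfg["seed"])
    base_source = sim.get("source")
    south = _scenario(sim.get("south"), seed=seed * 2 + 1,
                      base_source=base_source)
    north = _scenario(sim.get("north"), seed=seed * 2 + 2,
                      base_source=base_source)
    refs = load_references(cfg)
    synthesize_study(south, north, refs, out,
                     phased_males=bool(sim.get("phased_males", False)),
                     segments=tuple(sim.get("segments")))
    manifest = {
        "tool": f"haplomig {__version__}",
        "config_hash": config_hash(cfg),
        "seed": seed,
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in sorted(out.iterdir()) if p.name != "manifest.yaml"},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def run_call(cfg: dict, outdir) -> Path:
    """Discover and select SNPs, call haplotypes and Tpi genotypes."""
    out = Path(outdir) / "calls"
    out.mkdir(parents=True, exist_ok=True)
    paths = cfg.get("paths", {})
    seq_path = paths.get("specimens") or Path(outdir) / "simulate/specimens.fasta"
    meta_path = paths.get("metadata") or Path(outdir) / "simulate/metadata.csv"
    if not Path(seq_path).exists():
        raise ValidationError(f"specimen FASTA not found: {seq_path}")
    if not Path(meta_path).exists():
        raise ValidationError(f"metadata CSV not found: {meta_path}")
    records, _ = read_specimens(seq_path, meta_path,
                                delimiter=cfg["delimiter"])
    if not records:
        raise DataQualityError("no specimens read")
    refs = load_references(cfg)
    threshold = float(cfg["snp_threshold"])

    snp_rows, call_rows = [], []
    for segment in cfg["call"]["segments"]:
        sites = discover_snps(records, segment, refs[segment])
        selected = select_marker_sites(sites, threshold)
        for s in sites:
            snp_rows.append({
                "SNP": f"{segment}_{s.position}", "n": s.n_scored,
                "polymorphism": f"{s.major}/{s.minor}",
                "frequency": f"{round((1 - s.minor_frequency) * 100)}% {s.major}",
                "minor_frequency": round(s.minor_frequency, 6),
                "singleton": s.singleton,
                "selected": s in selected})
        if not selected:
            warnings.warn(f"{segment}: no marker sites above threshold "
                          f"{threshold}; haplotype calls skipped")
            continue
        for rec in sorted(records, key=lambda r: r.specimen_id):
            if not rec.sequence(segment):
                continue
            c = call_haplotype(rec, segment, selected, refs[segment])
            call_rows.append({
                "specimen_id": c.specimen_id,
                "collection_id": rec.collection_id, "state": rec.state,
                "year": rec.year, "segment": segment,
                "site_calls": "".join(c.site_calls),
                "label": c.label or "", "status": c.status})
    if not call_rows and not snp_rows:
        raise DataQualityError("no resolvable specimens in any segment")
    _write_csv(pd.DataFrame(snp_rows), out / "snp_summary.csv", cfg)
    _write_csv(pd.DataFrame(call_rows), out / "haplotype_calls.csv", cfg)

    tpi_rows = []
    if any(r.sequence("sTpi140") or r.sequence("sTpiE") for r in records):
        exon_sites = []
        if any(r.sequence("sTpiE") for r in records):
            exon_all = discover_snps(records, "sTpiE", refs["sTpiE"])
            exon_sites = select_marker_sites(exon_all, threshold=0.01)
        for rec in sorted(records, key=lambda r: r.specimen_id):
            if not (rec.sequence("sTpi140") or rec.sequence("sTpiE")):
                continue
            g = call_tpi(rec, exon_sites, refs)
            tpi_rows.append({
                "specimen_id": g.specimen_id,
                "collection_id": rec.collection_id, "state": rec.state,
                "year": rec.year, "i65_status": g.i65_status,
                "exon_calls": ";".join(
                    f"{p}={''.join(sorted(c)) if isinstance(c, frozenset) else c}"
                    for p, c in sorted(g.exon_calls.items()))})
    _write_csv(pd.DataFrame(tpi_rows), out / "tpi_calls.csv", cfg)
    return out


def run_analyze(cfg: dict, outdir) -> Path:
    """Frequency tables, M values, and regional statistical comparisons."""
    out = Path(outdir) / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    calls_path = Path(outdir) / "calls/haplotype_calls.csv"
    if not calls_path.exists():
        raise ValidationError(f"run 'call' first: {calls_path} not found")
    calls = pd.read_csv(calls_path, comment="#",
                        dtype={"label": str}, keep_default_na=False)
    if calls.empty:
        raise DataQualityError("haplotype call table is empty")

    grouping = cfg["analyze"]["grouping"]
    table = frequency_table(calls, grouping=grouping)
    freq_csv = table.counts.copy()
    freq_csv["n_resolved"] = table.n_resolved
    _write_csv(freq_csv.reset_index(), out / "frequency_table.csv", cfg)

    if cfg["analyze"].get("pies"):
        from .popstats import plot_state_pies
        plot_state_pies(table, out / "haplotype_pies.png")

    ms = m_results(table)
    m_df = pd.DataFrame([{"group": "/".join(map(str, m.group)),
                          "state": m.state, "count_focal": m.count_a,
                          "count_contrast": m.count_b, "M": round(m.m, 6)}
                         for m in ms])
    _write_csv(m_df, out / "m_by_collection.csv", cfg)

    report_lines = [f"haplomig {__version__} analysis report",
                    f"config={config_hash(cfg)} seed={cfg['seed']}", ""]
    pooled = table.counts.sum(axis=0)
    chi = chi_square_uniform(pooled.values)
    report_lines += [
        "Pooled haplotype counts: "
        + ", ".join(f"{k}={int(v)}" for k, v in pooled.items()),
        chi.summary(), ""]

    # per-collection frequency of each haplotype class, compared by ANOVA +
    # Tukey letters (are the class means genuinely distinct across groups?)
    freqs = table.frequencies()
    test_rows = [{"test": chi.name, "scheme": "", "statistic": chi.statistic,
                  "df": str(chi.df), "p_value": chi.p_value}]
    if len(freqs) >= 2 and freqs.shape[1] >= 2:
        groups = [freqs[c].values for c in freqs.columns]
        try:
            anova = one_way_anova(groups)
            tk = tukey_hsd(groups, labels=list(freqs.columns))
            letters = " ".join(f"{lab}:{tk.letters[lab]}"
                               for lab in freqs.columns)
            report_lines += [anova.summary(),
                             f"  r2={anova.extra['r2']:.4f}",
                             f"  Tukey letters: {letters}", ""]
            test_rows.append({"test": anova.name, "scheme": "",
                              "statistic": anova.statistic,
                              "df": str(anova.df), "p_value": anova.p_value})
        except DataQualityError as exc:
            report_lines += [f"ANOVA skipped: {exc}", ""]

    variant = cfg["test_variant"]
    scheme_names = cfg["analyze"]["schemes"]
    if scheme_names and ms and all(
            all(m.state in _SCHEMES[s]().excluded for s in scheme_names)
            for m in ms):
        raise DataQualityError(
            "all groups excluded from every regional scheme")
    for scheme_name in scheme_names:
        scheme = _SCHEMES[scheme_name]()
        try:
            res = regional_compare(ms, scheme, variant=variant)
        except DataQualityError as exc:
            report_lines += [f"{scheme.name}: skipped ({exc})", ""]
            continue
        report_lines += [res.summary(), ""]
        test_rows.append({"test": "regional_M", "scheme": scheme.name,
                          "statistic": res.statistic, "df": str(res.df),
                          "p_value": res.p_value})

    # i65del per-collection frequencies and the North/South contrast
    tpi_path = Path(outdir) / "calls/tpi_calls.csv"
    if tpi_path.exists():
        tpi = pd.read_csv(tpi_path, comment="#", keep_default_na=False)
        if not tpi.empty and (tpi["i65_status"] != "unknown").any():
            from .haplotyping import TpiGenotype
            mode = cfg["tpi_mode"]
            rows = []
            for (state, year, coll), sub in tpi.groupby(
                    ["state", "year", "collection_id"]):
                gts = [TpiGenotype(r.specimen_id, {}, r.i65_status)
                       for r in sub.itertuples()
                       if r.i65_status != "unknown"]
                if gts:
                    rows.append({"collection_id": coll, "state": state,
                                 "year": year, "n": len(gts),
                                 "i65del_freq": round(
                                     tpi_allele_frequency(gts, mode), 6)})
            i65_df = pd.DataFrame(rows)
            _write_csv(i65_df, out / "i65del_by_collection.csv", cfg)
            scheme = RegionScheme.north_south()
            north = [r.i65del_freq for r in i65_df.itertuples()
                     if scheme.mapping.get(r.state) == "North"]
            south = [r.i65del_freq for r in i65_df.itertuples()
                     if scheme.mapping.get(r.state) == "South"]
            if len(north) >= 2 and len(south) >= 2:
                res = two_sample_t(north, south, variant=variant)
                report_lines += [
                    f"i65del North vs South ({mode}): "
                    f"t={res.statistic:.4f} df={res.df:.0f} "
                    f"p={res.p_value:.4f}",
                    f"  North: n={len(north)} mean={pd.Series(north).mean():.2f}",
                    f"  South: n={len(south)} mean={pd.Series(south).mean():.2f}",
                    ""]
                test_rows.append({"test": "regional_i65del",
                                  "scheme": scheme.name,
                                  "statistic": res.statistic,
                                  "df": str(res.df), "p_value": res.p_value})

    _write_csv(pd.DataFrame(test_rows), out / "regional_tests.csv", cfg)
    with open(out / "report.txt", "w") as fh:
        fh.write("\n".join(report_lines) + "\n")
    return out


def run_power(cfg: dict, outdir) -> Path:
    """Founder-size power grid for the North/South regional comparison."""
    out = Path(outdir) / "power"
    out.mkdir(parents=True, exist_ok=True)
    p = cfg["power"]
    src_block = cfg["simulate"].get("source") or {}
    source = SourcePopulation(**{k: v for k, v in src_block.items()
                                 if k in SourcePopulation.__dataclass_fields__})
    grid = run_power_analysis(
        founder_sizes=p["founder_sizes"], replicates=int(p["replicates"]),
        source=source,
        n_collections_per_side=int(p["n_collections_per_side"]),
        n_sampled=int(p["n_sampled"]), alpha=float(p["alpha"]),
        seed=int(cfg["seed"]), variant=cfg["test_variant"])
    _write_csv(grid.table, out / "power_table.csv", cfg)
    return out
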