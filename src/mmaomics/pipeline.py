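"""End-to-end pipeline: simulate (optionally) then run every analysis stage
over flat TSV interchange files, producing a reproducible run manifest.

Stage order follows the data dependencies: cohort simulation -> phenomics
screens -> mixed-model expression scan -> cross-omics correlations ->
isotope tracing -> IP-MS network -> variant triage.  Any stage failure
aborts with a stage-tagged error; partial outputs are preserved.  All
randomness flows from the single manifest seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import cohort, ipms, lmm, phenomics, tracing, variants, xomics

__all__ = ["PipelineError", "ValidationError", "demo_config", "validate_inputs",
           "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


class ValidationError(ValueError):
    pass


DEFAULT_CONFIG = {
    "simulate": True,
    "n_case": 150,
    "n_other": 60,
    "n_control": 20,
    "n_genes": 4318,
    "screen_targets": ["css", "PI_plus", "age_at_onset_days"],
    "alpha": 0.05,
    "lmm_layer": "protein",
    "lmm_response": "PI_plus",
    "anchor_protein": "MMUT",
    "ipms_required": ["MMUT", "MMAA", "MMAB", "MCEE"],
    "ipms_min_required": 4,
    "ipms_forbidden": ["EV", "VLCAD"],
    "outlier_z": -3.0,
}


def demo_config(n_samples: int = 40, n_genes: int = 800) -> dict:
    """Desk-scale demo configuration (default: 40 samples, 800 genes)."""
    n_case = n_samples // 2
    n_control = max(n_samples // 5, 4)
    n_other = n_samples - n_case - n_control
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(n_case=n_case, n_other=n_other, n_control=n_control, n_genes=n_genes)
    return cfg


def load_config(path: str | Path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    loaded = yaml.safe_load(Path(path).read_text())
    if not isinstance(loaded, dict):
        raise ValidationError("config file must hold a mapping")
    unknown = set(loaded) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(loaded)
    return cfg


# ---------------------------------------------------------------------------
# input validation


_SCHEMAS = {
    "phenotypes.tsv": {"required": ["individual_id"]},
    "rna.tsv": {"required": ["gene"]},
    "protein.tsv": {"required": ["gene"]},
    "variants.tsv": {"required": variants.VARIANT_COLUMNS},
    "tracing.tsv": {"required": ["sample", "metabolite", "isotopologue", "area", "polarity"]},
    "tracing_standards.tsv": {"required": ["sample", "polarity", "area"]},
    "ipms_ids.tsv": {
        "required": ["protein", "bait", "replicate", "protein_probability",
                     "peptide_probabilities"]
    },
    "ipms_quant.tsv": {"required": ["protein"]},
    "groups.tsv": {"required": ["sample", "group"]},
}


def validate_inputs(paths: dict[str, Path | str]) -> list[dict]:
    """Schema-check every input table; returns row-level diagnostics
    (empty list = clean)."""
    report: list[dict] = []
    frames: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            report.append({"file": name, "row": None, "problem": "file not found"})
            continue
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:  # noqa: BLE001
            report.append({"file": name, "row": None, "problem": f"unreadable: {exc}"})
            continue
        frames[name] = df
        schema = _SCHEMAS.get(name)
        if schema:
            missing = [c for c in schema["required"] if c not in df.columns]
            if missing:
                report.append(
                    {"file": name, "row": None, "problem": f"missing columns {missing}"}
                )
    if "tracing.tsv" in frames:
        bad = frames["tracing.tsv"].index[frames["tracing.tsv"]["area"] < 0]
        for i in bad:
            report.append({"file": "tracing.tsv", "row": int(i), "problem": "negative peak area"})
    if "variants.tsv" in frames and "population_max_af" in frames["variants.tsv"]:
        af = frames["variants.tsv"]["population_max_af"]
        for i in frames["variants.tsv"].index[(af < 0) | (af > 1)]:
            report.append(
                {"file": "variants.tsv", "row": int(i), "problem": "allele frequency outside [0,1]"}
            )
    if "ipms_ids.tsv" in frames and "protein_probability" in frames["ipms_ids.tsv"]:
        pp = frames["ipms_ids.tsv"]["protein_probability"]
        for i in frames["ipms_ids.tsv"].index[(pp < 0) | (pp > 1)]:
            report.append(
                {"file": "ipms_ids.tsv", "row": int(i), "problem": "probability outside [0,1]"}
            )
    return report


# ---------------------------------------------------------------------------
# manifest


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    stages: dict[str, dict] = field(default_factory=dict)  # stage -> {seconds, records}
    defaults_in_effect: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
    manifest.outputs[path.name] = _digest(path)


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: dict, outdir: str | Path, seed: int = 0) -> RunManifest:
    """Execute every stage in dependency order and write the run manifest."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg,
        seed=seed,
        defaults_in_effect={
            "alpha": cfg["alpha"],
            "standardize_tol": 1e-6,
            "id_protein_prob": 0.99,
            "id_min_peptides": 2,
            "id_peptide_prob": 0.95,
            "variant_max_af": 0.01,
            "outlier_z": cfg["outlier_z"],
        },
    )

    def stage(name):
        start = time.perf_counter()

        def done(records: int):
            manifest.stages[name] = {
                "seconds": round(time.perf_counter() - start, 3),
                "records": int(records),
            }

        return done

    # -- simulate -----------------------------------------------------------
    done = stage("simulate")
    try:
        cc = cohort.CohortConfig(
            n_case=cfg["n_case"],
            n_other=cfg["n_other"],
            n_control=cfg["n_control"],
            n_genes=cfg["n_genes"],
            seed=seed,
        )
        bundle = cohort.simulate_cohort(cc)
        files = bundle.to_dir(outdir / "cohort")
        for f in files.values():
            manifest.outputs[str(f.relative_to(outdir))] = _digest(f)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc
    done(len(bundle.group_labels))

    report = validate_inputs({k: v for k, v in files.items() if k.endswith(".tsv")})
    if report:
        raise PipelineError("validate", f"input validation failed: {report[:5]}")

    # -- phenomics ----------------------------------------------------------
    done = stage("phenomics")
    try:
        pheno = bundle.phenotypes.copy()
        css = phenomics.css_scores(pheno)
        pheno["css"] = css["css"]
        _write(css.reset_index(), outdir / "css.tsv", manifest)
        corr = phenomics.correlation_matrix(pheno)
        _write(corr.reset_index(names="variable"), outdir / "phenotype_correlation.tsv", manifest)
        n_records = 0
        for target in cfg["screen_targets"]:
            screen = phenomics.association_screen(pheno, target=target, alpha=cfg["alpha"])
            _write(screen, outdir / f"screen_{target}.tsv", manifest)
            n_records += len(screen)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("phenomics", str(exc)) from exc
    done(n_records)

    # -- lmm ----------------------------------------------------------------
    done = stage("lmm")
    try:
        layer = bundle.protein if cfg["lmm_layer"] == "protein" else bundle.rna
        M = lmm.iterative_standardize(np.log2(layer))
        kin = lmm.sample_kinship(M)
        y = lmm.rank_inverse_normal(bundle.phenotypes[cfg["lmm_response"]])
        fits = lmm.lmm_scan(y, M, kin)
        _write(fits, outdir / "lmm_fits.tsv", manifest)
        mito = lmm.mito_filter(fits, cohort.MITO_GENES)
        _write(mito, outdir / "lmm_fits_mito.tsv", manifest)
        blup = lmm.predict_blup(
            y.loc[list(M.columns)],
            M.loc[["GLUD1", "OGDH"]].T,
            kin,
        )
        _write(blup.reset_index(names="sample"), outdir / "blup_ranking.tsv", manifest)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("lmm", str(exc)) from exc
    done(len(fits))

    # -- correlations -------------------------------------------------------
    done = stage("correlations")
    try:
        summary = xomics.cross_level_summary(np.log2(bundle.rna), np.log2(bundle.protein))
        pairs = xomics.paired_correlation_table(
            np.log2(bundle.rna), np.log2(bundle.protein), bundle.group_labels
        )
        _write(pairs, outdir / "transcript_protein_pairs.tsv", manifest)
        anchors = xomics.protein_pair_correlation(
            np.log2(bundle.protein),
            cfg["anchor_protein"],
            [g for g in cohort.NAMED_GENES if g != cfg["anchor_protein"]],
            bundle.group_labels.map(
                lambda g: cohort.GROUP_DEFICIENT
                if g == cohort.GROUP_DEFICIENT
                else "control"
            ),
        )
        _write(anchors, outdir / "anchor_correlations.tsv", manifest)
        (outdir / "correlation_summary.json").write_text(
            json.dumps(
                {
                    "median_gene_level": summary["median_gene_level"],
                    "median_sample_level": summary["median_sample_level"],
                    "n_pairs": summary["n_pairs"],
                    "n_samples": summary["n_samples"],
                },
                indent=1,
                sort_keys=True,
            )
        )
        manifest.outputs["correlation_summary.json"] = _digest(outdir / "correlation_summary.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("correlations", str(exc)) from exc
    done(len(pairs))

    # -- tracing ------------------------------------------------------------
    done = stage("tracing")
    try:
        vectors = tracing.isotopologue_fractions(bundle.tracing_peaks, bundle.tracing_standards)
        frac_rows = [
            {"sample": v.sample, "metabolite": v.metabolite,
             **{f"M{i}": f for i, f in enumerate(v.fractions)}}
            for v in vectors
        ]
        _write(pd.DataFrame(frac_rows).fillna(""), outdir / "isotopologue_fractions.tsv", manifest)
        ratios = [
            {"sample": v.sample, "ratio_m5_m4": tracing.citrate_ratio(v)}
            for v in vectors
            if v.metabolite == "citrate"
        ]
        _write(pd.DataFrame(ratios), outdir / "citrate_ratio.tsv", manifest)
        pools = (
            bundle.tracing_peaks.groupby(["sample", "metabolite"])["area"].sum().reset_index()
        )
        pools = pools.rename(columns={"area": "total"})
        pools["condition"] = pools["sample"].str.rsplit("_", n=1).str[0]
        comp = tracing.pool_size_compare(pools)
        _write(comp, outdir / "pool_comparison.tsv", manifest)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("tracing", str(exc)) from exc
    done(len(frac_rows))

    # -- ipms ---------------------------------------------------------------
    done = stage("ipms")
    try:
        pm = ipms.apply_id_thresholds(bundle.ipms_ids, bait_roles=cohort.BAIT_ROLES)
        flat = pm.detected.copy()
        flat.columns = [f"{b}_r{r}" for b, r in flat.columns]
        _write(flat.reset_index(), outdir / "presence_matrix.tsv", manifest)
        preys = ipms.specific_prey(
            pm,
            set(cfg["ipms_required"]),
            cfg["ipms_min_required"],
            set(cfg["ipms_forbidden"]),
        )
        regions = ipms.venn_partition(pm, cfg["ipms_required"])
        region_rows = [
            {"region": "&".join(sorted(k)), "n_proteins": len(v),
             "proteins": ";".join(sorted(v))}
            for k, v in sorted(regions.items(), key=lambda kv: "&".join(sorted(kv[0])))
        ]
        _write(pd.DataFrame(region_rows), outdir / "venn_regions.tsv", manifest)
        groups = {
            "MMUT": [f"MMUT_r{r}" for r in (1, 2, 3)],
            "EV": [f"EV_r{r}" for r in (1, 2, 3)],
            "VLCAD": [f"VLCAD_r{r}" for r in (1, 2, 3)],
        }
        quant_log = np.log2(bundle.ipms_quant)
        enr = ipms.anova_enrichment(quant_log, groups)
        _write(enr, outdir / "ipms_anova.tsv", manifest)
        G = ipms.build_network(preys, enr, pm, alpha=cfg["alpha"])
        edges = pd.DataFrame(
            [(u, v, d["weight"]) for u, v, d in G.edges(data=True)],
            columns=["bait", "prey", "weight"],
        ).sort_values(["bait", "prey"], kind="mergesort")
        _write(edges, outdir / "ipms_network_edges.tsv", manifest)
        nx.write_graphml(G, outdir / "ipms_network.graphml")
        manifest.outputs["ipms_network.graphml"] = _digest(outdir / "ipms_network.graphml")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ipms", str(exc)) from exc
    done(len(enr))

    # -- variants -----------------------------------------------------------
    done = stage("variants")
    try:
        filt = variants.filter_variants(bundle.variants)
        _write(filt.loc[filt["passed"]], outdir / "variants_passing.tsv", manifest)
        calls = variants.biallelic_calls(filt)
        calls_df = pd.DataFrame(
            [
                {
                    "individual_id": c.individual_id,
                    "gene": c.gene,
                    "call_type": c.call_type,
                    "alleles": ";".join(c.allele_ids),
                }
                for c in calls
            ]
        )
        _write(calls_df, outdir / "diagnosis_calls.tsv", manifest)
        census = variants.allele_type_counts(calls, filt)
        _write(
            pd.DataFrame(sorted(census.items()), columns=["consequence", "alleles"]),
            outdir / "allele_census.tsv",
            manifest,
        )
        burden = variants.mutational_burden(calls)
        _write(burden, outdir / "mutational_burden.tsv", manifest)
        outliers = variants.expression_outlier(np.log2(bundle.rna), cfg["outlier_z"])
        _write(outliers, outdir / "expression_outliers.tsv", manifest)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("variants", str(exc)) from exc
    done(len(calls_df))

    manifest.to_json(outdir / "manifest.json")
    return manifest
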