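"""End-to-end orchestration: QC -> kernels -> variance components -> GWAS ->
microbe associations, with a run manifest of checksums and timings.

The pipeline either simulates a cohort (config key ``simulate``) or loads
files (config key ``inputs``). Every stage writes its outputs under the run
directory and records a SHA-256 checksum, so identical configs reproduce
identical checksums for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .gwas import lmm_gwas, significance_thresholds, simple_m_eff
from .microbes import alpha_diversity, stratify_taxa, taxon_phenotype_association
from .relatedness import build_grm, build_mrm, filter_asvs, filter_genotypes, genetic_pcs
from .simulate import SimConfig, simulate_cohort
from .varcomp import build_covariates, estimate_h2, estimate_m2, permute_m2

_KNOWN_KEYS = {
    "simulate", "inputs", "out_dir", "seed", "maf_min", "snp_call_rate",
    "sample_call_rate", "asv_min_sample_fraction", "asv_min_mean_abundance",
    "n_pcs", "batch_col", "trait", "grm_cutoff", "simple_m_c",
    "simple_m_block", "alpha", "n_perm", "detection_high", "detection_low",
    "method_policy",
}


@dataclass
class AnalysisConfig:
    raw: dict

    def __post_init__(self) -> None:
        unknown = set(self.raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def get(self, key: str, default=None):
        return self.raw.get(key, default)


@dataclass
class RunManifest:
    config_hash: str
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path], seconds: float) -> None:
        self.stages.append(
            {
                "stage": stage,
                "seconds": round(seconds, 3),
                "outputs": {
                    name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in outputs.items()
                },
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config_hash": self.config_hash, "stages": self.stages}, indent=2
        ))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: AnalysisConfig) -> RunManifest:
    out = Path(config.get("out_dir", "holovar_run"))
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash)

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.time()
                self.outputs: dict[str, Path] = {}
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc_type is None:
                    manifest.record(name, self.outputs, time.time() - self.t0)
                else:
                    for p in self.outputs.values():
                        if p.exists():
                            p.rename(p.with_suffix(p.suffix + ".partial"))
                    manifest.record(name + " [FAILED]", {}, time.time() - self.t0)
                    manifest.write(out / "manifest.json")
                return False

        return _Timer()

    # ---- inputs
    with stage("inputs") as s:
        if "simulate" in config.raw:
            sim = SimConfig(**config.raw["simulate"])
            bundle = simulate_cohort(sim)
            G, A, pheno = bundle.genotypes, bundle.abundances, bundle.phenotypes
            hio.write_vcf(G, out / "genotypes.vcf")
            hio.write_abundance_tsv(A, out / "abundances.tsv")
            pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
            s.outputs = {"vcf": out / "genotypes.vcf",
                         "abundances": out / "abundances.tsv",
                         "phenotypes": out / "phenotypes.tsv"}
        else:
            inputs = config.raw["inputs"]
            G = hio.read_genotypes(
                inputs["genotypes"], inputs.get("genotype_format", "vcf")
            )
            A = hio.read_abundance_tsv(inputs["abundances"])
            pheno = hio.read_table(
                inputs["phenotypes"], required=("sample_id", config.get("trait", "trait"))
            )

    # ---- QC
    with stage("qc") as s:
        G = filter_genotypes(
            G,
            sample_call_rate=config.get("sample_call_rate", 0.9),
            snp_call_rate=config.get("snp_call_rate", 0.9),
            maf_min=config.get("maf_min", 0.01),
        )
        A = filter_asvs(
            A,
            min_sample_fraction=config.get("asv_min_sample_fraction", 0.01),
            min_mean_abundance=config.get("asv_min_mean_abundance", 1e-6),
        )
        keep = pheno["sample_id"].isin(G.sample_ids)
        pheno = pheno.loc[keep].set_index("sample_id").loc[G.sample_ids].reset_index()
        a_idx = [A.sample_ids.index(sid) for sid in G.sample_ids]
        from .containers import AbundanceTable

        A = AbundanceTable(
            rel_abundance=A.rel_abundance[a_idx],
            taxon_meta=A.taxon_meta,
            sample_ids=list(G.sample_ids),
        )

    # ---- kernels
    with stage("kernels") as s:
        grm = build_grm(G)
        mrm = build_mrm(A)
        pcs, _ = genetic_pcs(G, k=config.get("n_pcs", 5))
        hio.write_relationship_tsv(grm, out / "grm.tsv")
        hio.write_relationship_tsv(mrm, out / "mrm.tsv")
        s.outputs = {"grm": out / "grm.tsv", "mrm": out / "mrm.tsv"}

    trait = config.get("trait", "trait")
    batch_col = config.get("batch_col", "batch")

    # ---- variance components
    with stage("varcomp") as s:
        h2 = estimate_h2(pheno, grm, trait=trait, batch_col=batch_col)
        m2 = estimate_m2(pheno, mrm, trait=trait, batch_col=batch_col, pcs=pcs)
        rows = [
            {"component": "h2", "ratio": h2.ratio, "se": h2.se_ratio,
             "loglik": h2.loglik, "converged": h2.converged},
            {"component": "m2", "ratio": m2.ratio, "se": m2.se_ratio,
             "loglik": m2.loglik, "converged": m2.converged},
        ]
        n_perm = config.get("n_perm", 0)
        if n_perm:
            X = build_covariates(pheno, batch_col=batch_col, pcs=pcs)
            perm = permute_m2(
                pheno[trait].to_numpy(float), X, mrm, n_perm=n_perm,
                seed=config.get("seed", 0),
            )
            rows[1]["p_perm"] = perm.p_value
            rows[1]["mean_permuted"] = float(perm.permuted_ratios.mean())
        pd.DataFrame(rows).to_csv(out / "varcomp.tsv", sep="\t", index=False)
        s.outputs = {"varcomp": out / "varcomp.tsv"}

    # ---- GWAS
    with stage("gwas") as s:
        W = build_covariates(pheno, batch_col=batch_col, pcs=pcs)
        assoc = lmm_gwas(pheno[trait].to_numpy(float), W, G, grm)
        m_eff = simple_m_eff(
            G, c=config.get("simple_m_c", 0.995),
            block_size=config.get("simple_m_block", 1000),
        )
        thr = significance_thresholds(m_eff, alpha=config.get("alpha", 0.05))
        assoc.to_csv(out / "gwas.assoc.tsv", sep="\t", index=False)
        (out / "thresholds.json").write_text(json.dumps(
            {"m_eff": thr.m_eff, "genome_wide": thr.genome_wide,
             "suggestive": thr.suggestive}
        ))
        s.outputs = {"assoc": out / "gwas.assoc.tsv",
                     "thresholds": out / "thresholds.json"}

    # ---- microbe associations
    with stage("microbe_assoc") as s:
        div = alpha_diversity(A)
        coding = stratify_taxa(
            A, high=config.get("detection_high", 0.6),
            low=config.get("detection_low", 0.3),
        )
        assoc_m = taxon_phenotype_association(
            A, pheno[trait].to_numpy(float), coding,
            method_policy=config.get("method_policy", "spearman"),
        )
        div.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
        assoc_m.to_csv(out / "taxon_associations.tsv", sep="\t", index=False)
        s.outputs = {"diversity": out / "alpha_diversity.tsv",
                     "associations": out / "taxon_associations.tsv"}

    manifest.write(out / "manifest.json")
    return manifest
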