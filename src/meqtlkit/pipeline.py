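"""End-to-end orchestration of the mapping pipeline on a run directory.

Stages run in order prep -> relate -> assoc (scan, permutation FDR,
conditional) -> herit -> mediate, with optional stages skipped when their
inputs are absent. All randomness flows from one root seed via named
substreams; the manifest records seeds, row counts and the chosen FDR
threshold so a rerun with the same inputs and seed is bit-identical
(timestamps excluded).
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .assoc import conditional_stepwise, permutation_fdr
from .containers import CovariateTable
from .herit import cis_trans_grms, partition_pve
from .prep import beta_to_m, filter_probes, residualize_and_normalize
from .relate import centered_grm

__all__ = ["RunConfig", "run_all"]

DEFAULTS = dict(
    window_bp=50_000,
    maf_min=0.01,
    n_perm=10,
    fdr=0.05,
    mediation_fdr=0.05,
    seed=0,
    max_conditional=20,
    herit_max_features=200,
)


class RunConfig(dict):
    """Validated key-value run configuration (paths + stage parameters)."""

    REQUIRED = ["genotypes", "snp_map", "methylation", "feature_map"]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls({**DEFAULTS, **d})
        missing = [k for k in cls.REQUIRED if k not in cfg]
        if missing:
            raise ValueError(f"missing required config keys: {missing}")
        for key in cls.REQUIRED + ["covariates", "expression", "gwas"]:
            if key in cfg and not Path(cfg[key]).exists():
                raise FileNotFoundError(f"config path {key}={cfg[key]} not found")
        if not (0 < cfg["fdr"] < 1):
            raise ValueError("fdr must lie in (0,1)")
        return cfg


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage whose inputs are present; returns the run dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config["seed"]}
    t0 = time.time()
    try:
        # --- load + prep -------------------------------------------------
        stage = "prep"
        geno = mio.read_genotypes_tsv(config["genotypes"], config["snp_map"])
        pheno = mio.read_phenotypes_tsv(
            config["methylation"], config["feature_map"], scale="beta"
        )
        pheno, report = filter_probes(pheno, drop_sex_chroms=True)
        pheno.values = beta_to_m(pheno.values)
        pheno.scale = "M"
        if "covariates" in config:
            covars = mio.read_covariates_tsv(config["covariates"])
            names = config.get("covariate_names") or list(covars.table.columns)
            pheno, flagged = residualize_and_normalize(pheno, covars, names)
        else:
            covars, flagged = None, []
            from .prep import rank_inverse_normal

            pheno.values = np.apply_along_axis(
                rank_inverse_normal, 1, pheno.values
            )
            pheno.scale = "residual-normalized"
        (out / "prep").mkdir(exist_ok=True)
        pd.DataFrame(
            pheno.values, index=pheno.feature_ids, columns=pheno.sample_ids
        ).to_csv(out / "prep" / "normalized.tsv", sep="\t")
        manifest["stages"]["prep"] = {
            "n_features": pheno.n_features,
            "removed": report.removed,
            "flagged": len(flagged),
        }
        _log(stage, f"{pheno.n_features} features ready")

        # --- relate ------------------------------------------------------
        stage = "relate"
        if "kinship" in config and Path(config["kinship"]).exists():
            kin = mio.read_kinship_tsv(config["kinship"])
            kin.sample_ids = list(geno.sample_ids)
        else:
            kin = centered_grm(geno, maf_min=config["maf_min"])
        (out / "relate").mkdir(exist_ok=True)
        mio.write_kinship_tsv(out / "relate" / "kinship.tsv", kin)
        manifest["stages"]["relate"] = {"method": kin.method, "n": kin.n_samples}
        _log(stage, f"kinship ({kin.method}) ready")

        # --- assoc -------------------------------------------------------
        stage = "assoc"
        fdr_res = permutation_fdr(
            pheno, geno, kin,
            window_bp=config["window_bp"], maf_min=config["maf_min"],
            n_perm=config["n_perm"], target_fdr=config["fdr"],
            seed=config["seed"],
        )
        (out / "assoc").mkdir(exist_ok=True)
        mio.write_assoc_tsv(out / "assoc" / "associations.tsv",
                            fdr_res.scan.records)
        fdr_res.observed_min_p.to_csv(out / "assoc" / "min_p.tsv", sep="\t")
        (out / "assoc" / "fdr.json").write_text(
            json.dumps(
                {
                    "t_star": fdr_res.t_star,
                    "target_fdr": fdr_res.target_fdr,
                    "n_mecpgs": len(fdr_res.mecpgs),
                    "curve": fdr_res.curve.to_dict(orient="list"),
                },
                default=float,
            )
        )
        manifest["stages"]["assoc"] = {
            "t_star": fdr_res.t_star,
            "n_mecpgs": len(fdr_res.mecpgs),
            "n_meqtls": int(len(fdr_res.meqtls)),
        }
        _log(stage, f"t*={fdr_res.t_star:.3g}, {len(fdr_res.mecpgs)} meCpGs")

        # --- conditional -------------------------------------------------
        stage = "conditional"
        cond_rows = []
        if np.isfinite(fdr_res.t_star):
            ctx = fdr_res.scan.context
            fid_row = {f: i for i, f in enumerate(pheno.feature_ids)}
            for fid in fdr_res.mecpgs:
                cset = conditional_stepwise(
                    fid, pheno.values[fid_row[fid]], geno, ctx.eig,
                    fdr_res.t_star, window_idx=ctx.windows[fid],
                    max_signals=config["max_conditional"],
                )
                for rank, (_, r) in enumerate(cset.stats.iterrows(), 1):
                    cond_rows.append(
                        (fid, rank, r["snp"], r["beta"], r["se"], r["p"])
                    )
        cond = pd.DataFrame(
            cond_rows, columns=["feature", "rank", "snp", "beta", "se", "p"]
        )
        cond.to_csv(out / "assoc" / "conditional.tsv", sep="\t", index=False)
        manifest["stages"]["conditional"] = {"n_signals": len(cond)}
        _log(stage, f"{len(cond)} independent signals")

        # --- herit -------------------------------------------------------
        stage = "herit"
        rows = []
        feats = list(pheno.feature_ids)[: config["herit_max_features"]]
        fid_row = {f: i for i, f in enumerate(pheno.feature_ids)}
        for fid in feats:
            frow = pheno.feature_map.loc[fid]
            Kc, Kt = cis_trans_grms(
                geno, frow["chrom"], frow["pos"],
                window_bp=config["window_bp"], maf_min=config["maf_min"],
            )
            est = partition_pve(pheno.values[fid_row[fid]], Kc, Kt, feature=fid)
            rows.append(
                (fid, est.pve_total, est.pve_cis, est.pve_trans,
                 est.var_cis, est.var_trans, est.var_resid, est.converged)
            )
        herit = pd.DataFrame(
            rows,
            columns=["feature", "pve_total", "pve_cis", "pve_trans",
                     "varc", "vart", "vare", "converged"],
        )
        (out / "herit").mkdir(exist_ok=True)
        herit.to_csv(out / "herit" / "pve.tsv", sep="\t", index=False)
        manifest["stages"]["herit"] = {
            "n_features": len(herit),
            "median_pve_total": float(herit["pve_total"].median()) if len(herit) else None,
        }
        _log(stage, f"{len(herit)} features partitioned")

        # --- optional integrative stages ---------------------------------
        for name, needed in (
            ("colocal", ["expression"]),
            ("multicoloc", ["expression", "gwas"]),
            ("mediate", ["expression"]),
        ):
            if not all(k in config for k in needed):
                manifest["stages"][name] = "skipped (missing inputs)"
                _log(name, "skipped: inputs absent")

        manifest["elapsed_s"] = round(time.time() - t0, 2)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
        return out
    except Exception as err:
        raise RuntimeError(
            f"stage '{stage}' failed: {err}; rerun with "
            f"`meqtl run --config <file> --out {out}` after fixing inputs"
        ) from err
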