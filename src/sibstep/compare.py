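"""One-command pipeline comparing pedigree BLUP with single-step GBLUP.

Runs both evaluations on the same inputs and assembles the three report
surfaces: per-method variance components / heritability / mean accuracy,
per-family breeding-value means and SDs (the full-sib contrast), and
per-stratum relationship-distribution summaries for A and G.
"""

from __future__ import annotations

import json
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import SibstepError
from .genotype import build_G, build_H_inverse, qc_filter, read_genotypes
from .mixedmodel import (
    ModelSpec,
    apply_phenotype_filters,
    evaluate,
    em_reml,
    build_design,
    compute_heritability,
)
from .pedigree import build_A, build_A_inverse, extract_A22, read_pedigree, summarize_strata
from .simulate import SimConfig, SimData, simulate


@dataclass
class ComparisonReport:
    """Everything the comparison run reports, JSON-serialisable."""

    methods: dict
    families: list[dict]
    strata: dict
    headline: dict
    means: dict
    manifest: dict

    def to_dict(self) -> dict:
        return {
            "methods": self.methods,
            "families": self.families,
            "strata": self.strata,
            "headline": self.headline,
            "means": self.means,
            "manifest": self.manifest,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _family_stats(
    families: pd.DataFrame,
    pblup: pd.DataFrame,
    ssgblup: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait: str,
) -> list[dict]:
    ebv = pblup.set_index("animal")
    gebv = ssgblup.set_index("animal")
    phen = phenotypes.set_index("animal")[trait] if trait in phenotypes else None
    rows = []
    test = families[families.role == "test"]
    for fam, grp in test.groupby("family", sort=True):
        animals = grp["animal"].tolist()

        def stats(tab, col):
            vals = tab.loc[animals, col].to_numpy(float)
            return float(np.mean(vals)), (float(np.std(vals, ddof=1)) if len(vals) > 1 else None)

        ebv_m, ebv_sd = stats(ebv, "breeding_value")
        gebv_m, gebv_sd = stats(gebv, "breeding_value")
        acc_e, _ = stats(ebv, "accuracy")
        acc_g, _ = stats(gebv, "accuracy")
        row = {
            "family": fam,
            "sire": grp["sire"].iloc[0],
            "dam": grp["dam"].iloc[0],
            "n": len(animals),
            "ebv_mean": ebv_m,
            "ebv_sd": ebv_sd,
            "gebv_mean": gebv_m,
            "gebv_sd": gebv_sd,
            "acc_ebv_mean": acc_e,
            "acc_gebv_mean": acc_g,
        }
        if phen is not None:
            vals = phen.reindex(animals).dropna().to_numpy(float)
            row["phenotype_mean"] = float(vals.mean()) if vals.size else None
            row["phenotype_sd"] = (
                float(np.std(vals, ddof=1)) if vals.size > 1 else None
            )
        rows.append(row)
    return rows


def run_comparison(
    sim_cfg: SimConfig | None = None,
    data: SimData | None = None,
    paths: dict | None = None,
    outdir: str | None = None,
    accuracy_mode: str = "paper",
    blend_weight: float = 0.95,
    alpha_from: str = "fixed",
    components: tuple[float, float] | None = None,
    qc_kwargs: dict | None = None,
    age_range: tuple[float, float] = (26, 36),
) -> ComparisonReport:
    """Run the full PBLUP / ssGBLUP comparison.

    Inputs come from exactly one of ``sim_cfg`` (simulate), ``data`` (an
    in-memory :class:`SimData`), or ``paths`` (dict with ``pedigree``,
    ``phenotypes``, ``genotypes`` and optional ``families`` files).

    ``alpha_from="fixed"`` uses ``components`` (or the simulation truth);
    ``alpha_from="reml"`` estimates components per method by EM-REML.
    """
    if sum(x is not None for x in (sim_cfg, data, paths)) != 1:
        raise SibstepError("provide exactly one of sim_cfg, data, paths")

    truth_components = None
    if sim_cfg is not None:
        data = simulate(sim_cfg)
    if data is not None:
        ped = data.pedigree
        genotypes = data.genotypes
        phenotypes = data.phenotypes
        families = data.families
        trait = data.config.trait
        truth_components = (data.truth.sigma_a2, data.truth.sigma_e2)
        seed = data.config.seed
        sim_manifest = data.config.to_dict()
    else:
        ped = read_pedigree(paths["pedigree"])
        genotypes = read_genotypes(paths["genotypes"])
        phenotypes = pd.read_csv(paths["phenotypes"])
        if "families" in paths:
            families = pd.read_csv(paths["families"], dtype=str)
        else:
            families = None
        trait = paths.get("trait", "cwt")
        seed = None
        sim_manifest = None
    if genotypes is None:
        raise SibstepError("the comparison requires genotypes for the ssGBLUP arm")

    # ---- stage: phenotype filters -------------------------------------
    phenotypes = phenotypes.copy()
    phenotypes["animal"] = phenotypes["animal"].astype(str)
    filtered, filter_report = apply_phenotype_filters(phenotypes, age_range=age_range)
    if "role" in filtered.columns:
        eval_rows = filtered[filtered.role == "reference"]
        if data is not None and data.config.test_phenotyped:
            eval_rows = filtered[filtered.role.isin(["reference", "test"])]
    else:
        eval_rows = filtered
    eval_rows = eval_rows.dropna(subset=[trait])

    # ---- stage: pedigree matrices -------------------------------------
    A = build_A(ped)
    Ainv = build_A_inverse(ped)

    # ---- stage: genotype QC and genomic matrices ----------------------
    geno_qc, qc_report = qc_filter(genotypes, **(qc_kwargs or {}))
    G = build_G(geno_qc)
    A22 = extract_A22(A, G.ids)
    Hinv = build_H_inverse(Ainv, A22, G, blend_weight=blend_weight)

    # ---- stage: variance components -----------------------------------
    reml_info: dict = {}
    if alpha_from == "fixed":
        if components is None:
            components = truth_components
        if components is None:
            raise SibstepError("alpha_from='fixed' needs components (or simulated truth)")
        comp = {"pblup": components, "ssgblup": components}
    elif alpha_from == "reml":
        comp = {}
        spec0 = ModelSpec(trait=trait)
        y, X, _ = build_design(eval_rows, spec0)
        eval_ids = eval_rows["animal"].astype(str).tolist()
        a_idx = A.index_of(eval_ids)
        cov_a = A.to_dense()[np.ix_(a_idx, a_idx)]
        est_a = em_reml(y, X, cov_a)
        comp["pblup"] = (est_a.sigma_a2, est_a.sigma_e2)
        # phenotyped animals genotyped -> their H block is the blended G*;
        # fall back to inverting H^-1 otherwise
        gset = set(G.ids)
        if all(a in gset for a in eval_ids):
            g_idx = G.index_of(eval_ids)
            gstar = blend_weight * G.to_dense() + (1 - blend_weight) * A22.to_dense()
            cov_h = gstar[np.ix_(g_idx, g_idx)]
        else:
            h_idx = Hinv.index_of(eval_ids)
            hfull = np.linalg.inv(Hinv.to_dense())
            cov_h = hfull[np.ix_(h_idx, h_idx)]
        est_h = em_reml(y, X, cov_h)
        comp["ssgblup"] = (est_h.sigma_a2, est_h.sigma_e2)
        reml_info = {
            "pblup": {"n_iter": est_a.n_iter, "converged": est_a.converged},
            "ssgblup": {"n_iter": est_h.n_iter, "converged": est_h.converged},
        }
    else:
        raise SibstepError(f"unknown alpha_from {alpha_from!r}")

    # ---- stage: both evaluations --------------------------------------
    results = {}
    for method, kinv in (("pblup", Ainv), ("ssgblup", Hinv)):
        sa2, se2 = comp[method]
        spec = ModelSpec(trait=trait, sigma_a2=sa2, sigma_e2=se2)
        results[method] = evaluate(spec, eval_rows, kinv, accuracy_mode=accuracy_mode)

    # ---- stage: report -------------------------------------------------
    if families is None:
        # derive families from parent pairs of genotyped, non-evaluated animals
        eval_set = set(eval_rows["animal"])
        rows = []
        for a in G.ids:
            if a in eval_set:
                continue
            s, d = ped.parents_of(a)
            rows.append({"animal": a, "sire": s or "0", "dam": d or "0", "role": "test"})
        families = pd.DataFrame(rows)
        if not families.empty:
            pair_ids = {
                pair: f"F{k + 1:02d}"
                for k, pair in enumerate(
                    sorted(set(zip(families.sire, families.dam)))
                )
            }
            families["family"] = [
                pair_ids[(s, d)] for s, d in zip(families.sire, families.dam)
            ]

    test_ids = families.loc[families.role == "test", "animal"].tolist()
    genotyped_unphenotyped = [a for a in test_ids if a in set(G.ids)]

    methods = {}
    for method in ("pblup", "ssgblup"):
        res = results[method]
        h2, sp2 = compute_heritability(res.sigma_a2, res.sigma_e2)
        tab = res.table.set_index("animal")
        acc = tab.loc[genotyped_unphenotyped, "accuracy"].to_numpy(float)
        methods[method] = {
            "sigma_a2": res.sigma_a2,
            "sigma_e2": res.sigma_e2,
            "sigma_p2": sp2,
            "h2": h2,
            "accuracy_mean": float(acc.mean()) if acc.size else None,
            "accuracy_sd": float(np.std(acc, ddof=1)) if acc.size > 1 else None,
        }

    fam_stats = _family_stats(
        families, results["pblup"].table, results["ssgblup"].table, phenotypes, trait
    )

    strata = {
        "A": summarize_strata(extract_A22(A, G.ids), ped),
        "G": summarize_strata(G, ped),
    }

    ebv_sds = [r["ebv_sd"] for r in fam_stats if r["ebv_sd"] is not None]
    gebv_sds = [r["gebv_sd"] for r in fam_stats if r["gebv_sd"] is not None]
    headline = {
        "accuracy_gap": (
            methods["ssgblup"]["accuracy_mean"] - methods["pblup"]["accuracy_mean"]
            if methods["pblup"]["accuracy_mean"] is not None
            else None
        ),
        "max_within_family_ebv_sd": max(ebv_sds) if ebv_sds else None,
        "min_within_family_gebv_sd": min(gebv_sds) if gebv_sds else None,
    }

    # family-mean roll-ups: both weightings, since they differ in general
    sizes = np.array([r["n"] for r in fam_stats], dtype=float)
    ebv_means = np.array([r["ebv_mean"] for r in fam_stats], dtype=float)
    gebv_means = np.array([r["gebv_mean"] for r in fam_stats], dtype=float)
    means = {}
    if sizes.size:
        means = {
            "ebv_family_weighted": float(ebv_means.mean()),
            "ebv_animal_weighted": float((ebv_means * sizes).sum() / sizes.sum()),
            "gebv_family_weighted": float(gebv_means.mean()),
            "gebv_animal_weighted": float((gebv_means * sizes).sum() / sizes.sum()),
        }

    manifest = {
        "sibstep_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "trait": trait,
        "accuracy_mode": accuracy_mode,
        "blend_weight": blend_weight,
        "alpha_from": alpha_from,
        "phenotype_filter": filter_report,
        "qc": {
            "n_snp_in": qc_report.n_snp_in,
            "n_snp_out": qc_report.n_snp_out,
            "n_removed_maf": qc_report.n_removed_maf,
            "n_removed_missing": qc_report.n_removed_missing,
            "n_removed_hwe": qc_report.n_removed_hwe,
            "thresholds": qc_report.thresholds,
        },
        "reml": reml_info,
        "sim_config": sim_manifest,
    }

    report = ComparisonReport(
        methods=methods,
        families=fam_stats,
        strata=strata,
        headline=headline,
        means=means,
        manifest=manifest,
    )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        report.to_json(os.path.join(outdir, "report.json"))
        qc_report.write_tsv(os.path.join(outdir, "qc_report.tsv"))
        fam_lookup = families.set_index("animal")["family"] if "family" in families else None
        for method in ("pblup", "ssgblup"):
            tab = results[method].table.copy()
            if fam_lookup is not None:
                tab["family"] = [fam_lookup.get(a, "") for a in tab["animal"]]
            tab.to_csv(os.path.join(outdir, f"{method}_results.tsv"), sep="\t", index=False)
        if data is not None:
            data.write(os.path.join(outdir, "inputs"))
    return report
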