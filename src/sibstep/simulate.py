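"""Synthetic embryo-transfer-style data generator.

Produces a two-tier population: a reference tier of phenotyped, genotyped
half-sib families, and a test tier of genotyped, phenotype-free full-sib
families whose sires are drawn from the reference sires (so pedigree ties
connect the tiers).  Genotypes segregate by Mendelian gene dropping from
HWE founders; breeding values are either genic (SNP effects) or follow the
parent-average + Mendelian-sampling recursion.  All randomness flows from a
single integer seed through one PCG64 generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SibstepError
from .genotype import GenotypeMatrix, compute_freqs
from .pedigree import Pedigree, inbreeding, read_pedigree


@dataclass
class SimConfig:
    """Generator parameters.  ``seed`` is mandatory for reproducibility."""

    seed: int
    # test tier: full-sib families
    n_families: int = 16
    family_size_range: tuple[int, int] = (10, 10)
    n_test_sires: int = 5
    n_shared_test_dams: int = 2  # dams used by two families (maternal half-sibs)
    # reference tier: paternal half-sib families
    n_reference: int = 2000
    n_ref_sires: int = 50
    n_ref_dams: int = 500
    # genome
    n_snp: int = 2000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int | None = None  # None = every SNP carries an effect
    # trait architecture
    trait: str = "cwt"
    target_h2: float = 0.4
    sigma_p2: float = 100.0
    mean: float = 450.0
    tbv_mode: str = "genic"  # or "pedigree"
    mendelian_scale: float = 1.0  # 0 switches Mendelian sampling off (pedigree mode)
    # fixed effects
    n_birth_years: int = 3
    n_birth_months: int = 12
    n_places: int = 3
    year_effect_sd: float = 3.0
    month_effect_sd: float = 2.0
    place_effect_sd: float = 3.0
    age_slope: float = 1.5
    age_range_months: tuple[int, int] = (26, 36)
    # which animals get phenotypes / genotypes
    test_phenotyped: bool = False
    genotype_reference: bool = True
    genotype_test: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SibstepError("SimConfig.seed is mandatory")
        if not 0 < self.target_h2 < 1:
            raise SibstepError("target_h2 must lie in (0, 1)")
        for name in ("n_families", "n_reference", "n_snp", "n_ref_sires",
                     "n_ref_dams", "n_test_sires"):
            if getattr(self, name) < 1:
                raise SibstepError(f"{name} must be >= 1")

    @property
    def sigma_a2(self) -> float:
        return self.target_h2 * self.sigma_p2

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.target_h2) * self.sigma_p2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests."""

    tbv: pd.Series  # true breeding value per animal (all pedigree animals)
    snp_effects: np.ndarray | None
    mendelian: pd.Series | None  # recorded Mendelian draws (pedigree mode)
    founder_freqs: np.ndarray | None
    sigma_a2: float
    sigma_e2: float
    realized_h2: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "sigma_a2": self.sigma_a2,
            "sigma_e2": self.sigma_e2,
            "realized_h2": self.realized_h2,
            "seed": self.seed,
            "tbv": {k: float(v) for k, v in self.tbv.items()},
        }
        if self.snp_effects is not None:
            payload["snp_effects"] = [float(v) for v in self.snp_effects]
        if self.founder_freqs is not None:
            payload["founder_freqs"] = [float(v) for v in self.founder_freqs]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SimData:
    """Bundle of everything one simulation run produces."""

    config: SimConfig
    pedigree: Pedigree
    families: pd.DataFrame  # animal, family, role, sire, dam
    genotypes: GenotypeMatrix | None
    phenotypes: pd.DataFrame
    truth: SimTruth

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.pedigree.to_frame()[["animal", "sire", "dam"]].to_csv(
            os.path.join(outdir, "pedigree.csv"), index=False
        )
        self.families.to_csv(os.path.join(outdir, "families.csv"), index=False)
        self.phenotypes.to_csv(os.path.join(outdir, "phenotypes.csv"), index=False)
        if self.genotypes is not None:
            self.genotypes.write_tsv(os.path.join(outdir, "genotypes.tsv"))
        self.truth.to_json(os.path.join(outdir, "truth.json"))


# ---------------------------------------------------------------------------
# pedigree generation
# ---------------------------------------------------------------------------


def generate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Build the two-tier pedigree and its family table.

    Reference animals form paternal half-sib families (``n_ref_sires`` sires
    over ``n_ref_dams`` dams); test families are full-sib groups whose sires
    are re-used across families (and are reference sires, tying the tiers
    together) and whose dams may be shared pairwise to create maternal
    half-sib links.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    records: list[tuple[str, str, str]] = []
    fam_rows: list[dict] = []

    ref_sires = [f"RS{i + 1:03d}" for i in range(cfg.n_ref_sires)]
    ref_dams = [f"RD{i + 1:04d}" for i in range(cfg.n_ref_dams)]

    for k in range(cfg.n_reference):
        animal = f"REF{k + 1:05d}"
        sire = ref_sires[int(rng.integers(cfg.n_ref_sires))]
        dam = ref_dams[int(rng.integers(cfg.n_ref_dams))]
        records.append((animal, sire, dam))
        fam_rows.append(
            {"animal": animal, "family": "", "role": "reference", "sire": sire, "dam": dam}
        )

    # test-family parents: sires re-used from the reference sires
    n_sires = min(cfg.n_test_sires, cfg.n_ref_sires)
    test_sires = [ref_sires[i] for i in range(n_sires)]
    n_shared = min(cfg.n_shared_test_dams, cfg.n_families // 2)
    n_dams = cfg.n_families - n_shared
    test_dams = [f"TD{i + 1:03d}" for i in range(n_dams)]
    dam_assign = list(range(n_dams)) + list(range(n_shared))  # last n_shared reuse dams

    lo, hi = cfg.family_size_range
    for f in range(cfg.n_families):
        sire = test_sires[f % len(test_sires)]
        dam = test_dams[dam_assign[f]]
        size = int(rng.integers(lo, hi + 1))
        for k in range(size):
            animal = f"T{f + 1:02d}_{k + 1:02d}"
            records.append((animal, sire, dam))
            fam_rows.append(
                {"animal": animal, "family": f"F{f + 1:02d}", "role": "test",
                 "sire": sire, "dam": dam}
            )

    ped = read_pedigree(records)
    families = pd.DataFrame(fam_rows)
    return ped, families


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def drop_genes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mendelian gene dropping over the whole pedigree.

    Founders are sampled from Hardy-Weinberg proportions at per-SNP founder
    frequencies drawn uniformly from ``founder_maf_range``; every offspring
    allele is drawn uniformly from the parent's two alleles, independently
    per locus (no linkage).  Returns ``(dosages, founder_freqs)`` with
    dosages for every pedigree animal in pedigree order.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    m = cfg.n_snp
    lo, hi = cfg.founder_maf_range
    freqs = rng.uniform(lo, hi, size=m)
    n = ped.n
    pat = np.empty((n, m), dtype=np.int8)  # paternal allele per locus
    mat = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i] - 1, ped.dam[i] - 1
        if s >= 0:
            pick = rng.integers(0, 2, size=m)
            pat[i] = np.where(pick == 0, pat[s], mat[s])
        else:
            pat[i] = (rng.random(m) < freqs).astype(np.int8)
        if d >= 0:
            pick = rng.integers(0, 2, size=m)
            mat[i] = np.where(pick == 0, pat[d], mat[d])
        else:
            mat[i] = (rng.random(m) < freqs).astype(np.int8)
    dosages = (pat + mat).astype(np.float64)
    return dosages, freqs


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    ped: Pedigree,
    cfg: SimConfig,
    dosages: np.ndarray | None = None,
    founder_freqs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate true breeding values and phenotype records.

    Two TBV modes: ``genic`` (additive SNP effects on centred dosages,
    rescaled so the phenotyped-tier TBV variance equals ``sigma_a2``) and
    ``pedigree`` (founder TBVs Normal(0, sigma_a2), offspring by the
    parent-average recursion with a recorded Mendelian-sampling draw of
    variance ``sigma_a2 / 2 * (1 - (F_s + F_d) / 2)``).

    Phenotype = mean + class effects (birth year/month, place) + age slope x
    age + TBV + residual.  Every animal gets a phenotype row; the ``role``
    split into evaluation/test sets is the caller's concern.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = ped.n
    sa2, se2 = cfg.sigma_a2, cfg.sigma_e2
    snp_effects = None
    mendelian = None

    if cfg.tbv_mode == "genic":
        if dosages is None or founder_freqs is None:
            raise SibstepError("genic TBV mode requires dosages and founder freqs")
        m = dosages.shape[1]
        eff = rng.normal(0.0, 1.0, size=m)
        if cfg.n_qtl is not None and cfg.n_qtl < m:
            off = rng.choice(m, size=m - cfg.n_qtl, replace=False)
            eff[off] = 0.0
        centred = dosages - 2.0 * founder_freqs
        raw = centred @ eff
        sd_raw = float(np.std(raw))
        if sd_raw <= 0:
            raise SibstepError("degenerate genic TBV: zero variance")
        scale = np.sqrt(sa2) / sd_raw
        tbv = raw * scale
        snp_effects = eff * scale
    elif cfg.tbv_mode == "pedigree":
        tbv = np.zeros(n)
        mend = np.zeros(n)
        F = inbreeding(ped)
        for i in range(n):
            s, d = ped.sire[i] - 1, ped.dam[i] - 1
            if s < 0 and d < 0:
                tbv[i] = rng.normal(0.0, np.sqrt(sa2))
                continue
            pa = 0.0
            fs = F[s] if s >= 0 else 0.0
            fd = F[d] if d >= 0 else 0.0
            if s >= 0:
                pa += 0.5 * tbv[s]
            if d >= 0:
                pa += 0.5 * tbv[d]
            if s >= 0 and d >= 0:
                msv = 0.5 * sa2 * (1.0 - 0.5 * (fs + fd))
            else:
                msv = 0.75 * sa2  # one parent unknown: its half contributes fully
            mend[i] = cfg.mendelian_scale * rng.normal(0.0, np.sqrt(msv))
            tbv[i] = pa + mend[i]
        mendelian = pd.Series(mend, index=list(ped.ids))
    else:
        raise SibstepError(f"unknown tbv_mode {cfg.tbv_mode!r}")

    years = rng.integers(0, cfg.n_birth_years, size=n)
    months = rng.integers(0, cfg.n_birth_months, size=n)
    places = rng.integers(0, cfg.n_places, size=n)
    ages = rng.integers(cfg.age_range_months[0], cfg.age_range_months[1] + 1, size=n)
    year_eff = rng.normal(0.0, cfg.year_effect_sd, size=cfg.n_birth_years)
    month_eff = rng.normal(0.0, cfg.month_effect_sd, size=cfg.n_birth_months)
    place_eff = rng.normal(0.0, cfg.place_effect_sd, size=cfg.n_places)
    resid = rng.normal(0.0, np.sqrt(se2), size=n)
    mean_age = 0.5 * (cfg.age_range_months[0] + cfg.age_range_months[1])
    pheno = (
        cfg.mean
        + year_eff[years]
        + month_eff[months]
        + place_eff[places]
        + cfg.age_slope * (ages - mean_age)
        + tbv
        + resid
    )
    table = pd.DataFrame(
        {
            "animal": list(ped.ids),
            cfg.trait: pheno,
            "birth_year": 2015 + years,
            "birth_month": 1 + months,
            "slaughter_age_months": ages,
            "slaughter_place": [f"P{p + 1}" for p in places],
        }
    )
    var_tbv = float(np.var(tbv))
    realized_h2 = var_tbv / (var_tbv + se2)
    truth = SimTruth(
        tbv=pd.Series(tbv, index=list(ped.ids)),
        snp_effects=snp_effects,
        mendelian=mendelian,
        founder_freqs=founder_freqs,
        sigma_a2=sa2,
        sigma_e2=se2,
        realized_h2=realized_h2,
        seed=cfg.seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# one-call wrapper
# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig) -> SimData:
    """Run the full generator: pedigree, genotypes, phenotypes, truth.

    Phenotype rows are emitted for all animals with a ``role`` column;
    reference animals are the evaluation records, test animals keep their
    simulated phenotype for reporting but are excluded from evaluation when
    ``cfg.test_phenotyped`` is False (pre-slaughter evaluation).
    """
    rng = np.random.default_rng(cfg.seed)
    ped, families = generate_pedigree(cfg, rng)
    need_geno = cfg.genotype_reference or cfg.genotype_test or cfg.tbv_mode == "genic"
    dosages = founder_freqs = None
    genotypes = None
    if need_geno:
        dosages, founder_freqs = drop_genes(ped, cfg, rng)
    phenos, truth = simulate_phenotypes(ped, cfg, dosages, founder_freqs, rng)

    role = families.set_index("animal")["role"]
    phenos["role"] = [role.get(a, "founder") for a in phenos["animal"]]
    fam = families.set_index("animal")["family"]
    phenos["family"] = [fam.get(a, "") for a in phenos["animal"]]

    if dosages is not None:
        geno_ids = []
        if cfg.genotype_reference:
            geno_ids += families.loc[families.role == "reference", "animal"].tolist()
        if cfg.genotype_test:
            geno_ids += families.loc[families.role == "test", "animal"].tolist()
        # keep pedigree order for a stable genotyped sub-order shared by G and A22
        order = {a: i for i, a in enumerate(ped.ids)}
        geno_ids = sorted(geno_ids, key=order.__getitem__)
        idx = [order[a] for a in geno_ids]
        sub = dosages[idx, :]
        genotypes = GenotypeMatrix(
            ids=tuple(geno_ids),
            snp_ids=tuple(f"SNP{j + 1:05d}" for j in range(cfg.n_snp)),
            dosages=sub,
            freqs=compute_freqs(sub),
        )
    return SimData(
        config=cfg,
        pedigree=ped,
        families=families,
        genotypes=genotypes,
        phenotypes=phenos,
        truth=truth,
    )
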