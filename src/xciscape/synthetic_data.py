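"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the five input families the analysis consumes —
allelic read counts, sex-bias effect estimates, sex-biased regulatory
elements, TAD intervals and gene annotation — on a synthetic chromosome, so
every pipeline stage is testable without external data.

Generative model
----------------
Genes are laid inside contiguous non-overlapping TADs, with a pseudoautosomal
block (PAR1) at the chromosome start. Each gene carries a latent
escape propensity on the logit scale,

    l_gt = mu_class(g) + u_TAD(g) + u_gene(g) + u_tissue(g, t),

with u_TAD ~ N(0, tad_sd^2) shared by all genes in a TAD (this is what makes
escape similar within TADs), u_gene ~ N(0, gene_sd^2) and a per-gene-x-tissue
jitter u_tissue ~ N(0, tissue_sd^2). The inactive-X expression fraction is
f_gt = 0.5 * sigmoid(l_gt) in (0, 0.5), so the true escape scale is
1 - AE_true = 0.5 + f_gt and the escape call threshold 1-AE >= 0.6
corresponds to l >= logit(0.2). NPX genes are planted as consistently
escaping, variable (propensity at the call boundary) or silenced in
configured fractions; PAR genes sit high on the propensity scale.

Reads per gene x tissue x individual are total ~ Poisson(read_depth_mean)
(floored at 1) with inactive-X reads beta-binomial(total, f, overdispersion);
the reference allele is the inactive or active haplotype with equal
probability, and AE follows from the counts.

Sex effects couple to the *true* escape magnitude for escape-class genes
only: male-biased PAR genes get beta = par_bias_intercept +
coupling_slope_par * AE_true (deeper silencing in females -> stronger male
bias), female-biased NPX escape genes get beta = npx_bias_intercept +
coupling_slope_npx * (1 - AE_true - 0.5) (fuller escape -> stronger female
bias), both plus N(0, beta_noise_sd). Silenced and variable genes draw beta
independently of AE. The LFSR is a deterministic monotone stand-in,
2 * (1 - Phi(|beta| / beta_noise_sd)), which puts planted biased genes far
below the 0.05 significance cutoff and gives null genes a uniform LFSR.

Regulatory elements are placed immediately adjacent to a configured fraction
of sex-biased genes with a matching effect sign and adjusted p < 0.2, plus
sign-free background elements that do not reach significance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .config import ParBoundaries
from .io_harmonize import compute_ae


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study, with units and defaults.

    Dimensions default to the scale of the emulated study: a small
    pseudoautosomal gene set, a few hundred NPX genes, tens of TADs,
    25 tissues and 3 informative (skewed-XCI) individuals. tad_sd / gene_sd /
    tissue_sd are logit-scale standard deviations of the escape-propensity
    components; coupling slopes are in beta units per unit of allelic
    expression; frac_escape_npx = 0.12 and frac_variable_npx = 0.15 mirror
    the consensus fractions of consistent and variable escape on the X.
    """

    n_par_genes: int = 15
    n_npx_genes: int = 300
    n_tads: int = 40
    n_tissues: int = 25
    n_individuals: int = 3
    read_depth_mean: float = 100.0
    tad_sd: float = 1.0
    gene_sd: float = 0.5
    tissue_sd: float = 0.3
    coupling_slope_par: float = 4.0
    coupling_slope_npx: float = -4.0
    beta_noise_sd: float = 0.05
    frac_escape_npx: float = 0.12
    frac_variable_npx: float = 0.15
    overdispersion: float = 0.02
    seed: int = 1
    # secondary knobs (kept fixed across analyses)
    mu_par: float = 1.2
    mu_escape: float = 0.6
    mu_variable: float = -1.386  # logit(0.2): the escape-call boundary
    mu_silenced: float = -3.0
    par_bias_intercept: float = 0.3
    npx_bias_intercept: float = -0.3
    frac_par_biased: float = 0.85
    frac_npx_escape_biased: float = 0.7
    frac_silenced_female: float = 0.11
    frac_silenced_male: float = 0.07
    frac_are_linked: float = 0.6
    tad_width: int = 500_000
    gene_length: int = 10_000
    n_are_tissues: int = 4

    def __post_init__(self) -> None:
        for name in ("n_npx_genes", "n_tads", "n_tissues", "n_individuals"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_par_genes < 0:
            raise ValueError("n_par_genes must be >= 0")
        if self.read_depth_mean <= 0:
            raise ValueError("read_depth_mean must be positive")
        if self.beta_noise_sd <= 0:
            raise ValueError("beta_noise_sd must be positive")
        for name in ("tad_sd", "gene_sd", "tissue_sd", "overdispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "frac_escape_npx", "frac_variable_npx", "frac_par_biased",
            "frac_npx_escape_biased", "frac_silenced_female",
            "frac_silenced_male", "frac_are_linked",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_escape_npx + self.frac_variable_npx > 1.0:
            raise ValueError("frac_escape_npx + frac_variable_npx exceeds 1")
        if self.frac_silenced_female + self.frac_silenced_male > 1.0:
            raise ValueError("silenced-gene bias fractions exceed 1")
        if self.n_tads > self.n_par_genes + self.n_npx_genes:
            raise ValueError("more TADs than genes")


@dataclass
class SyntheticBundle:
    """Generated inputs plus the latent truth needed to score recovery."""

    genes: pd.DataFrame
    tads: pd.DataFrame
    ae_table: pd.DataFrame
    sexbias_table: pd.DataFrame
    are_table: pd.DataFrame
    truth: dict[str, Any]

    @property
    def par_boundaries(self) -> ParBoundaries:
        return ParBoundaries(
            par1_end=self.truth["par1_end"],
            par2_start=self.truth["chrom_length"],
        )


def lfsr_standin(beta, beta_noise_sd: float):
    """Deterministic monotone LFSR stand-in: 2 * (1 - Phi(|beta| / sd))."""
    z = np.abs(np.asarray(beta, dtype=float)) / beta_noise_sd
    return 2.0 * (1.0 - ndtr(z))


def generate(config: SimConfig) -> SyntheticBundle:
    """Generate a full synthetic input bundle. Deterministic given the config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.n_par_genes + cfg.n_npx_genes

    # --- chromosome layout: contiguous TADs, PAR1 block first -------------
    if cfg.n_par_genes > 0:
        n_par_tads = int(round(cfg.n_tads * cfg.n_par_genes / n_genes))
        n_par_tads = min(max(n_par_tads, 1), cfg.n_tads - 1)
    else:
        n_par_tads = 0
    tad_rows = []
    for k in range(cfg.n_tads):
        tad_rows.append(
            {
                "tad_id": f"TAD{k + 1:03d}",
                "chrom": "chrSYN",
                "start": k * cfg.tad_width,
                "end": (k + 1) * cfg.tad_width,
                "rank": k + 1,
            }
        )
    tads = pd.DataFrame(tad_rows)
    par1_end = n_par_tads * cfg.tad_width
    chrom_length = cfg.n_tads * cfg.tad_width

    # --- gene placement: round-robin over the region's TADs ---------------
    gene_rows = []
    margin = cfg.gene_length
    for region, count, tad_lo, tad_hi in (
        ("PAR1", cfg.n_par_genes, 0, n_par_tads),
        ("NPX", cfg.n_npx_genes, n_par_tads, cfg.n_tads),
    ):
        n_region_tads = tad_hi - tad_lo
        if count == 0 or n_region_tads == 0:
            continue
        for i in range(count):
            k = tad_lo + (i % n_region_tads)
            lo = k * cfg.tad_width + margin
            hi = (k + 1) * cfg.tad_width - margin - cfg.gene_length
            start = int(rng.integers(lo, hi))
            gene_rows.append(
                {
                    "region": region,
                    "tad_id": f"TAD{k + 1:03d}",
                    "start": start,
                    "end": start + cfg.gene_length,
                }
            )
    genes = pd.DataFrame(gene_rows).sort_values("start", kind="stable").reset_index(drop=True)
    ids = []
    counters = {"PAR1": 0, "NPX": 0}
    for region in genes["region"]:
        counters[region] += 1
        prefix = "PARG" if region == "PAR1" else "NPXG"
        ids.append(f"{prefix}{counters[region]:04d}")
    genes.insert(0, "gene_id", ids)
    genes["strand"] = "unknown"

    # --- latent escape propensity -----------------------------------------
    is_par = (genes["region"] == "PAR1").to_numpy()
    n_npx = int((~is_par).sum())
    xci_class = np.where(is_par, "par", "silenced").astype(object)
    npx_idx = np.nonzero(~is_par)[0]
    n_esc = int(round(cfg.frac_escape_npx * n_npx))
    n_var = int(round(cfg.frac_variable_npx * n_npx))
    shuffled = rng.permutation(npx_idx)
    xci_class[shuffled[:n_esc]] = "escape"
    xci_class[shuffled[n_esc:n_esc + n_var]] = "variable"
    mu_map = {
        "par": cfg.mu_par,
        "escape": cfg.mu_escape,
        "variable": cfg.mu_variable,
        "silenced": cfg.mu_silenced,
    }
    mu = np.asarray([mu_map[c] for c in xci_class])
    tad_effect = {t: rng.normal(0.0, cfg.tad_sd) for t in tads["tad_id"]}
    u_tad = np.asarray([tad_effect[t] for t in genes["tad_id"]])
    u_gene = rng.normal(0.0, cfg.gene_sd, size=n_genes)
    tissues = [f"tissue{t + 1:02d}" for t in range(cfg.n_tissues)]
    u_tissue = rng.normal(0.0, cfg.tissue_sd, size=(n_genes, cfg.n_tissues))
    logit_f = (mu + u_tad + u_gene)[:, None] + u_tissue
    f_true = 0.5 * expit(logit_f)  # Xi/total fraction, in (0, 0.5)
    ae_true = 0.5 - f_true

    # --- allelic read counts ----------------------------------------------
    individuals = [f"IND{i + 1}" for i in range(cfg.n_individuals)]
    n_obs = n_genes * cfg.n_tissues * cfg.n_individuals
    total = rng.poisson(cfg.read_depth_mean, size=(n_genes, cfg.n_tissues, cfg.n_individuals))
    total = np.maximum(total, 1)
    f3 = np.broadcast_to(f_true[:, :, None], total.shape)
    if cfg.overdispersion > 0:
        rho = cfg.overdispersion
        a = f3 * (1.0 - rho) / rho
        b = (1.0 - f3) * (1.0 - rho) / rho
        p = rng.beta(a, b)
    else:
        p = f3
    xi_reads = rng.binomial(total, p)
    # per gene x individual, the reference haplotype is Xi or Xa at random
    ref_is_xi = rng.random((n_genes, 1, cfg.n_individuals)) < 0.5
    ref_reads = np.where(ref_is_xi, xi_reads, total - xi_reads)
    ae_obs = compute_ae(ref_reads.ravel(), total.ravel()).reshape(total.shape)
    g_idx, t_idx, i_idx = np.meshgrid(
        np.arange(n_genes), np.arange(cfg.n_tissues), np.arange(cfg.n_individuals),
        indexing="ij",
    )
    ae_table = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy()[g_idx.ravel()],
            "tissue": np.asarray(tissues, dtype=object)[t_idx.ravel()],
            "individual": np.asarray(individuals, dtype=object)[i_idx.ravel()],
            "sample_id": [
                f"{ind}-{tis}"
                for ind, tis in zip(
                    np.asarray(individuals, dtype=object)[i_idx.ravel()],
                    np.asarray(tissues, dtype=object)[t_idx.ravel()],
                )
            ],
            "ref_reads": ref_reads.ravel(),
            "total_reads": total.ravel(),
            "ae": ae_obs.ravel(),
        }
    )

    # --- sex-bias effects ---------------------------------------------------
    biased = np.zeros(n_genes, dtype=bool)
    direction = np.full(n_genes, "none", dtype=object)
    u = rng.random(n_genes)
    for i in range(n_genes):
        if xci_class[i] == "par":
            if u[i] < cfg.frac_par_biased:
                biased[i], direction[i] = True, "male"
        elif xci_class[i] == "escape":
            if u[i] < cfg.frac_npx_escape_biased:
                biased[i], direction[i] = True, "female"
        else:  # silenced / variable: bias independent of escape magnitude
            if u[i] < cfg.frac_silenced_female:
                biased[i], direction[i] = True, "female"
            elif u[i] < cfg.frac_silenced_female + cfg.frac_silenced_male:
                biased[i], direction[i] = True, "male"

    noise = rng.normal(0.0, cfg.beta_noise_sd, size=(n_genes, cfg.n_tissues))
    indep_mag = rng.uniform(0.3, 1.0, size=n_genes)
    beta = np.empty((n_genes, cfg.n_tissues))
    for i in range(n_genes):
        if not biased[i]:
            beta[i] = noise[i]
        elif xci_class[i] == "par":
            # deeper silencing (larger AE_true) -> stronger male bias
            beta[i] = cfg.par_bias_intercept + cfg.coupling_slope_par * ae_true[i] + noise[i]
        elif xci_class[i] == "escape":
            # fuller escape (larger 1-AE_true) -> more negative beta
            beta[i] = (
                cfg.npx_bias_intercept
                + cfg.coupling_slope_npx * (0.5 - ae_true[i])
                + noise[i]
            )
        else:
            sign = 1.0 if direction[i] == "male" else -1.0
            beta[i] = sign * indep_mag[i] + noise[i]
    lfsr = lfsr_standin(beta, cfg.beta_noise_sd)
    mean_expr = np.exp(rng.normal(3.0, 1.0, size=n_genes))[:, None] * np.exp(
        rng.normal(0.0, 0.2, size=(n_genes, cfg.n_tissues))
    )
    gg, tt = np.meshgrid(np.arange(n_genes), np.arange(cfg.n_tissues), indexing="ij")
    sexbias_table = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy()[gg.ravel()],
            "tissue": np.asarray(tissues, dtype=object)[tt.ravel()],
            "beta_mash": beta.ravel(),
            "lfsr": lfsr.ravel(),
            "mean_expression": mean_expr.ravel(),
        }
    )

    # --- regulatory elements ------------------------------------------------
    are_tissues = tissues[: cfg.n_are_tissues]
    are_rows = []
    counter = 0
    link = rng.random(n_genes)
    fp = rng.random(n_genes)
    for i in range(n_genes):
        start = int(genes.loc[i, "end"]) + 1_000
        if biased[i] and link[i] < cfg.frac_are_linked:
            counter += 1
            sign = 1.0 if direction[i] == "male" else -1.0
            are_rows.append(
                {
                    "element_id": f"ARE{counter:04d}",
                    "start": start,
                    "end": start + 2_000,
                    "tissue": are_tissues[counter % len(are_tissues)],
                    "sex_effect": sign * float(rng.uniform(0.5, 2.0)),
                    "p_adj": float(rng.uniform(0.0, 0.19)),
                    "nearest_gene": genes.loc[i, "gene_id"],
                }
            )
        elif not biased[i] and fp[i] < 0.03:
            # occasional significant element near an unbiased gene
            counter += 1
            are_rows.append(
                {
                    "element_id": f"ARE{counter:04d}",
                    "start": start,
                    "end": start + 2_000,
                    "tissue": are_tissues[counter % len(are_tissues)],
                    "sex_effect": float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)),
                    "p_adj": float(rng.uniform(0.0, 0.19)),
                    "nearest_gene": genes.loc[i, "gene_id"],
                }
            )
        elif fp[i] > 0.8:
            # background element that does not reach significance
            counter += 1
            are_rows.append(
                {
                    "element_id": f"ARE{counter:04d}",
                    "start": start,
                    "end": start + 2_000,
                    "tissue": are_tissues[counter % len(are_tissues)],
                    "sex_effect": float(rng.normal(0.0, 0.5)),
                    "p_adj": float(rng.uniform(0.2, 1.0)),
                    "nearest_gene": genes.loc[i, "gene_id"],
                }
            )
    are_table = pd.DataFrame(
        are_rows,
        columns=["element_id", "start", "end", "tissue", "sex_effect", "p_adj", "nearest_gene"],
    )

    truth = {
        "config": asdict(cfg),
        "par1_end": par1_end,
        "chrom_length": chrom_length,
        "gene_truth": pd.DataFrame(
            {
                "gene_id": genes["gene_id"],
                "region": genes["region"],
                "tad_id": genes["tad_id"],
                "xci_class": xci_class,
                "u_tad": u_tad,
                "u_gene": u_gene,
                "biased": biased,
                "bias_direction": direction,
            }
        ),
        "f_true": pd.DataFrame(f_true, index=genes["gene_id"], columns=tissues),
        "tad_effects": tad_effect,
        "coupling": {
            "slope_par": cfg.coupling_slope_par,
            "slope_npx": cfg.coupling_slope_npx,
        },
    }
    return SyntheticBundle(
        genes=genes[["gene_id", "start", "end", "region", "strand", "tad_id"]],
        tads=tads,
        ae_table=ae_table,
        sexbias_table=sexbias_table,
        are_table=are_table,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Hand-checkable fixture
# ---------------------------------------------------------------------------

def toy_fixture() -> SyntheticBundle:
    """Fixed 8-gene, 3-TAD, 2-tissue, 2-individual bundle.

    Every number is hand-set so that pairwise distances, cross-tabulations
    and classifications can be enumerated on paper. One gene x tissue pair
    (NPXG0002 in tissue01) is planted as 'variable': the two individuals
    disagree on its XCI call. The PAR1 block is the first TAD
    ([0, 1000)); TADs are [0,1000), [1000,2000), [2000,3000).
    """
    tads = pd.DataFrame(
        {
            "tad_id": ["TAD001", "TAD002", "TAD003"],
            "chrom": ["chrSYN"] * 3,
            "start": [0, 1000, 2000],
            "end": [1000, 2000, 3000],
            "rank": [1, 2, 3],
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": ["PARG0001", "PARG0002", "PARG0003",
                        "NPXG0001", "NPXG0002", "NPXG0003", "NPXG0004", "NPXG0005"],
            "start": [100, 400, 700, 1100, 1400, 1700, 2100, 2600],
            "end": [200, 500, 800, 1200, 1500, 1800, 2200, 2700],
            "region": ["PAR1"] * 3 + ["NPX"] * 5,
            "strand": ["unknown"] * 8,
            "tad_id": ["TAD001"] * 3 + ["TAD002"] * 3 + ["TAD003"] * 2,
        }
    )
    # (gene, tissue, individual, ref_reads, total_reads); AE = |0.5 - ref/total|
    count_spec = [
        ("PARG0001", 4, 10),   # AE 0.10, 1-AE 0.90  escape
        ("PARG0002", 3, 10),   # AE 0.20, 1-AE 0.80  escape
        ("PARG0003", 1, 20),   # AE 0.45, 1-AE 0.55  silenced
        ("NPXG0001", 2, 10),   # AE 0.30, 1-AE 0.70  escape
        ("NPXG0002", None, None),  # planted variable; filled below
        ("NPXG0003", 1, 50),   # AE 0.48, 1-AE 0.52  silenced
        ("NPXG0004", 0, 10),   # AE 0.50, 1-AE 0.50  silenced
        ("NPXG0005", 9, 20),   # AE 0.05, 1-AE 0.95  escape
    ]
    rows = []
    for gene, ref, tot in count_spec:
        for tissue in ("tissue01", "tissue02"):
            for ind in ("IND1", "IND2"):
                if gene == "NPXG0002":
                    if tissue == "tissue01" and ind == "IND1":
                        ref, tot = 8, 10    # AE 0.30 -> escape
                    elif tissue == "tissue01" and ind == "IND2":
                        ref, tot = 19, 20   # AE 0.45 -> silenced
                    else:
                        ref, tot = 3, 20    # AE 0.35 -> escape (both individuals)
                rows.append(
                    {
                        "gene_id": gene,
                        "tissue": tissue,
                        "individual": ind,
                        "sample_id": f"{ind}-{tissue}",
                        "ref_reads": ref,
                        "total_reads": tot,
                        "ae": compute_ae(ref, tot),
                    }
                )
    ae_table = pd.DataFrame(rows)
    bias_spec = {
        "PARG0001": (1.2, 0.001),
        "PARG0002": (0.8, 0.01),
        "PARG0003": (0.1, 0.5),
        "NPXG0001": (-0.9, 0.001),
        "NPXG0002": (-0.2, 0.3),
        "NPXG0003": (-0.5, 0.02),
        "NPXG0004": (0.05, 0.9),
        "NPXG0005": (-1.5, 0.0001),
    }
    sexbias_table = pd.DataFrame(
        [
            {
                "gene_id": g,
                "tissue": tissue,
                "beta_mash": b,
                "lfsr": l,
                "mean_expression": 20.0 + 2.0 * i,
            }
            for i, (g, (b, l)) in enumerate(bias_spec.items())
            for tissue in ("tissue01", "tissue02")
        ]
    )
    are_table = pd.DataFrame(
        [
            {"element_id": "ARE0001", "start": 1200, "end": 1300, "tissue": "tissue01",
             "sex_effect": 1.0, "p_adj": 0.05, "nearest_gene": "PARG0001"},
            {"element_id": "ARE0002", "start": 2710, "end": 2810, "tissue": "tissue02",
             "sex_effect": -1.0, "p_adj": 0.10, "nearest_gene": "NPXG0005"},
            {"element_id": "ARE0003", "start": 1810, "end": 1910, "tissue": "tissue01",
             "sex_effect": -0.4, "p_adj": 0.50, "nearest_gene": "NPXG0003"},
        ]
    )
    truth = {
        "config": None,
        "par1_end": 1000,
        "chrom_length": 3000,
        "planted_variable": [("NPXG0002", "tissue01")],
        "gene_truth": pd.DataFrame(
            {
                "gene_id": genes["gene_id"],
                "region": genes["region"],
                "tad_id": genes["tad_id"],
                "xci_class": ["par", "par", "silenced", "escape", "variable",
                              "silenced", "silenced", "escape"],
                "biased": [True, True, False, True, False, True, False, True],
                "bias_direction": ["male", "male", "none", "female", "none",
                                   "female", "none", "female"],
            }
        ),
    }
    return SyntheticBundle(
        genes=genes, tads=tads, ae_table=ae_table,
        sexbias_table=sexbias_table, are_table=are_table, truth=truth,
    )


# ---------------------------------------------------------------------------
# Writing bundles in the dialects the readers accept
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the five input files (+ truth JSON) in reader-compatible dialects.

    Gene annotation is written 1-based inclusive (the convention
    ``read_gene_annotation`` expects by default); the TAD file is plain BED.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ae": outdir / "ae.tsv",
        "sexbias": outdir / "sexbias.tsv",
        "are": outdir / "are.tsv",
        "tads": outdir / "tads.bed",
        "genes": outdir / "genes.tsv",
        "truth": outdir / "truth.json",
    }
    bundle.ae_table.to_csv(paths["ae"], sep="\t", index=False)
    bundle.sexbias_table.to_csv(paths["sexbias"], sep="\t", index=False)
    bundle.are_table.to_csv(paths["are"], sep="\t", index=False)
    bundle.tads[["chrom", "start", "end"]].to_csv(
        paths["tads"], sep="\t", index=False, header=False
    )
    ann = bundle.genes[["gene_id", "start", "end", "region", "strand"]].copy()
    ann["start"] = ann["start"] + 1  # back to 1-based inclusive
    ann.to_csv(paths["genes"], sep="\t", index=False)
    truth_json = {
        k: v for k, v in bundle.truth.items() if not isinstance(v, pd.DataFrame)
    }
    truth_json["gene_truth"] = bundle.truth["gene_truth"].to_dict(orient="list")
    if isinstance(bundle.truth.get("f_true"), pd.DataFrame):
        truth_json["f_true"] = {
            "index": list(bundle.truth["f_true"].index),
            "columns": list(bundle.truth["f_true"].columns),
            "values": bundle.truth["f_true"].to_numpy().tolist(),
        }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1, default=float)
    return paths
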