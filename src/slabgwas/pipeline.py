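"""End-to-end orchestration: QC, step-1 model fitting, step-2 testing, evaluation.

Step 1 estimates variance components (randomized Haseman–Elston for
quantitative traits, ELBO grid search for binary), fits the whole-genome
spike-and-slab regression jointly across traits, and produces warm-started
leave-one-chromosome-out refits and residuals.  Step 2 scans every retained
variant with the proportional score statistic, calibrates per trait against
plain regression on an unrelated homogeneous subset, and applies the
approximate-Firth fallback to binary traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logit

from . import association as assoc
from .genotype_io import (
    AdjustedMatrix,
    GenotypeMatrix,
    residualize_covariates,
    standardize,
)
from .svi import (
    LocoResiduals,
    OptimizerConfig,
    PriorSpec,
    fit_svi,
    heldout_residual_variance,
    loco_residuals,
)
from .variance import DEFAULT_H2_GRID, grid_search_h2, rhe_estimate

logger = logging.getLogger(__name__)

__all__ = [
    "Step1Options",
    "Step1Result",
    "EvaluationReport",
    "hwe_exact_test",
    "qc_filter",
    "run_step1",
    "run_step2",
    "evaluate",
]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy–Weinberg test P-value for one biallelic variant.

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on the allele counts.
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_minor + n_het  # minor allele count
    if n_a > n:  # ensure we condition on the rarer allele
        n_a = 2 * n - n_a
    hets = np.arange(n_a % 2, n_a + 1, 2)
    hom_min = (n_a - hets) // 2
    hom_maj = n - hom_min - hets
    valid = hom_maj >= 0
    hets, hom_min, hom_maj = hets[valid], hom_min[valid], hom_maj[valid]
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_het]
    if obs.size == 0:
        return 0.0
    return float(min(p[p <= obs[0] * (1 + 1e-12)].sum(), 1.0))


def qc_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    missingness_max: float = 0.01,
    hwe_p_min: float = 1e-15,
) -> GenotypeMatrix:
    """Drop variants failing MAF, call-rate or Hardy–Weinberg filters."""
    from .genotype_io import MISSING

    n = G.n_samples
    keep = []
    n_fail = {"maf": 0, "missing": 0, "hwe": 0}
    for j, v in enumerate(G.variants):
        col = G.dosages[:, j]
        miss = float(np.mean(col == MISSING))
        if miss > missingness_max:
            n_fail["missing"] += 1
            continue
        if not (v.maf >= maf_min):
            n_fail["maf"] += 1
            continue
        if hwe_p_min > 0:
            obs = col[col != MISSING]
            counts = np.bincount(obs, minlength=3)
            het, hom1, hom0 = int(counts[1]), int(counts[2]), int(counts[0])
            hom_minor, hom_major = (
                (hom1, hom0) if hom1 <= hom0 else (hom0, hom1)
            )
            if hwe_exact_test(het, hom_minor, hom_major) < hwe_p_min:
                n_fail["hwe"] += 1
                continue
        keep.append(j)
    logger.info("qc_filter: removed %s of %d variants", n_fail, G.n_variants)
    if not keep:
        raise ValueError(f"all variants removed by QC ({n_fail})")
    out = G.subset_variants(np.asarray(keep))
    out.sample_info = getattr(G, "sample_info", None)
    return out


# ---------------------------------------------------------------------------
# Step 1
# ---------------------------------------------------------------------------


@dataclass
class Step1Options:
    slab_prob: float = 0.01
    h2_grid: tuple = DEFAULT_H2_GRID
    rhe_vectors: int = 50
    holdout_fraction: float = 0.25
    standardize_mode: str = "empirical"
    # variant-exclusion regions "chrom:start-end" (e.g. an HLA mask),
    # removed before variance-component estimation and model fitting
    exclude_regions: tuple = ()
    # n_mc_samples=0 selects the exact expected quadratic for linear fits;
    # logistic fits fall back to one antithetic pair automatically
    optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(n_mc_samples=0)
    )
    loco_optimizer: OptimizerConfig | None = None
    seed: int = 0
    dtype: type = np.float32

    def loco_cfg(self) -> OptimizerConfig:
        if self.loco_optimizer is not None:
            return self.loco_optimizer
        base = self.optimizer
        return OptimizerConfig(
            learning_rate=base.learning_rate,
            batch_size=base.batch_size,
            max_epochs=max(base.max_epochs // 4, 5),
            tol=base.tol,
            patience=base.patience,
            n_mc_samples=base.n_mc_samples,
            antithetic=base.antithetic,
        )


@dataclass
class Step1Result:
    trait_names: list
    trait_type: str
    X: AdjustedMatrix
    chrom_labels: np.ndarray
    h2: np.ndarray
    prior: PriorSpec
    whole_posterior: object
    loco: LocoResiduals
    y_adj: np.ndarray | None = None
    y_raw: np.ndarray | None = None
    offsets: np.ndarray | None = None
    grid_elbos: list | None = None
    # the genotype matrix the fit actually used (after any region mask);
    # step 2 must index variants against this, not the caller's copy
    genotypes: GenotypeMatrix | None = None


def run_step1(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait_type: str = "quantitative",
    covariates: np.ndarray | None = None,
    options: Step1Options | None = None,
) -> Step1Result:
    """Model fitting: variance components, whole-genome fit, LOCO refits.

    ``pheno`` holds one column per trait, aligned to ``G.samples``.  Traits
    with fewer than 100 non-missing samples are skipped with a warning; the
    remaining traits must be jointly complete.
    """
    opts = options or Step1Options()
    names = [c for c in pheno.columns if c not in ("FID", "IID")]
    kept = []
    for c in names:
        if pheno[c].notna().sum() < 100:
            warnings.warn(f"trait {c}: fewer than 100 non-missing samples; skipped")
        else:
            kept.append(c)
    if not kept:
        raise ValueError("no usable traits")
    if opts.exclude_regions:
        masked = _region_mask(G, opts.exclude_regions)
        if masked.any():
            logger.info("excluding %d variant(s) in masked regions",
                        int(masked.sum()))
            G = G.subset_variants(np.flatnonzero(~masked))
    Y = pheno[kept].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("traits must be complete after skipping sparse ones")

    X = standardize(G, mode=opts.standardize_mode, covariates=covariates,
                    dtype=opts.dtype)
    chrom_labels = np.array(
        [G.variants[j].chromosome for j in X.retained]
    )
    chroms = list(dict.fromkeys(chrom_labels.tolist()))
    m = X.n_variants

    if trait_type == "quantitative":
        y_adj = residualize_covariates(Y, covariates)
        y_adj = y_adj / y_adj.std(axis=0, keepdims=True)
        vcs = rhe_estimate(X.values, y_adj, opts.rhe_vectors, seed=opts.seed)
        if not isinstance(vcs, list):
            vcs = [vcs]
        h2 = np.array([vc.h2 for vc in vcs])
        prior = PriorSpec.from_h2(h2, m, opts.slab_prob)
        y_fit = y_adj.astype(opts.dtype)
        heldout = heldout_residual_variance(
            X.values, y_fit, prior, opts.optimizer,
            holdout_fraction=opts.holdout_fraction, seed=opts.seed + 11,
        )
        offsets = None
        grid_elbos = None
    elif trait_type == "binary":
        offsets = np.column_stack(
            [assoc.logistic_covariate_offset(Y[:, t], covariates)
             for t in range(Y.shape[1])]
        )
        # the grid comparison needs near-converged fits: an under-fitted
        # ELBO systematically favors the smallest prior variance
        grid_cfg = opts.loco_cfg()
        grid_cfg.max_epochs = max(grid_cfg.max_epochs,
                                  opts.optimizer.max_epochs // 2)
        vcs, _ = grid_search_h2(
            X.values, Y, offset=offsets, grid=opts.h2_grid,
            slab_prob=opts.slab_prob, optimizer_cfg=grid_cfg,
            seed=opts.seed + 7,
        )
        if not isinstance(vcs, list):
            vcs = [vcs]
        h2 = np.array([vc.h2 for vc in vcs])
        grid_elbos = [vc.grid_elbos for vc in vcs]
        for name, vc in zip(kept, vcs):
            logger.info("grid search %s: %s -> h2=%.2f", name, vc.grid_elbos, vc.h2)
        prior = PriorSpec.from_h2(h2, m, opts.slab_prob)
        y_fit = Y.astype(opts.dtype)
        heldout = None
    else:
        raise ValueError(f"unknown trait type {trait_type!r}")

    model = "linear" if trait_type == "quantitative" else "logistic"
    whole_q, rep = fit_svi(
        X.values, y_fit, prior, opts.optimizer, model=model,
        offset=offsets, seed=opts.seed + 1,
    )
    logger.info("whole-genome fit: %d epochs, converged=%s", rep.epochs,
                rep.converged)

    posteriors = {}
    loco_cfg = opts.loco_cfg()
    for k, c in enumerate(chroms):
        posteriors[c], _ = fit_svi(
            X.values, y_fit, prior, loco_cfg, init=whole_q,
            exclude_chromosome=c, chromosomes=chrom_labels, model=model,
            offset=offsets, seed=opts.seed + 100 + k,
        )

    loco = loco_residuals(
        X.values,
        y_adj if trait_type == "quantitative" else Y,
        posteriors,
        model=model,
        chromosomes=chrom_labels,
        offset=offsets,
        heldout_resid_var=heldout,
    )
    return Step1Result(
        trait_names=kept,
        trait_type=trait_type,
        X=X,
        chrom_labels=chrom_labels,
        h2=h2,
        prior=prior,
        whole_posterior=whole_q,
        loco=loco,
        y_adj=y_adj if trait_type == "quantitative" else None,
        y_raw=Y if trait_type == "binary" else None,
        offsets=offsets,
        grid_elbos=grid_elbos,
        genotypes=G,
    )


def _region_mask(G: GenotypeMatrix, regions) -> np.ndarray:
    """Boolean mask of variants falling in any "chrom:start-end" region."""
    mask = np.zeros(G.n_variants, dtype=bool)
    for region in regions:
        chrom, span = region.split(":")
        start, end = (int(v) for v in span.split("-"))
        for j, v in enumerate(G.variants):
            if v.chromosome == chrom and start <= v.position <= end:
                mask[j] = True
    return mask


# ---------------------------------------------------------------------------
# Step 2
# ---------------------------------------------------------------------------


def _calibration_variants(m: int, rng: np.random.Generator,
                          fraction: float = 0.05, minimum: int = 1000):
    k = min(max(int(round(fraction * m)), minimum), m)
    return np.sort(rng.choice(m, size=k, replace=False))


def _relatedness_adjustment(X: AdjustedMatrix, subset: np.ndarray,
                            rng: np.random.Generator) -> float:
    """N_eff(full) / N(subset) with kinship-detected pairs up to third degree."""
    n, m = X.n_samples, X.n_variants
    cols = rng.choice(m, size=min(m, 5000), replace=False)
    pairs = assoc.detect_related_pairs(np.ascontiguousarray(X.values[:, cols]))
    n_eff = assoc.effective_sample_size(n, pairs)
    return n_eff / len(subset)


def run_step2(
    G: GenotypeMatrix,
    step1: Step1Result,
    covariates: np.ndarray | None = None,
    calibration_subset: np.ndarray | None = None,
    seed: int = 0,
    firth_fallback: bool = True,
    weights: np.ndarray | None = None,
) -> dict:
    """Score-test every retained variant for every step-1 trait.

    ``calibration_subset`` holds row indices of the unrelated homogeneous
    samples used for the plain-regression reference (all samples by
    default).  ``weights`` (quantitative traits only) switches to weighted
    least squares with Huber–White sandwich variances — the
    participation-bias correction — recalibrated against weighted
    regression on the subset.  Returns
    {trait name: (results DataFrame, CalibrationFactor)}.
    """
    if weights is not None and step1.trait_type != "quantitative":
        raise ValueError("participation weights apply to quantitative traits")
    if step1.genotypes is not None:
        G = step1.genotypes
    rng = np.random.default_rng(seed)
    X = step1.X
    n = X.n_samples
    subset = (
        np.arange(n) if calibration_subset is None
        else np.asarray(calibration_subset)
    )
    if subset.size < 2:
        raise ValueError("degenerate calibration subset")
    chrom_labels = step1.chrom_labels
    m = X.n_variants
    calib = _calibration_variants(m, rng)
    rel_adj = _relatedness_adjustment(X, subset, rng)

    C_sub = covariates[subset] if covariates is not None else None
    Xsub = np.ascontiguousarray(X.values[subset])
    if C_sub is not None and step1.trait_type == "quantitative":
        Xsub_adj = residualize_covariates(Xsub[:, calib], C_sub).astype(X.values.dtype)
    else:
        Xsub_adj = Xsub[:, calib]

    traits = step1.trait_names
    t_count = len(traits)
    raw = np.empty((m, t_count))
    beta = np.empty((m, t_count))
    for c in dict.fromkeys(chrom_labels.tolist()):
        cols = np.flatnonzero(chrom_labels == c)
        Xc = X.values[:, cols]
        if step1.trait_type == "quantitative" and weights is not None:
            yt = step1.loco.residuals[c]
            for t in range(t_count):
                bt, _, ct = assoc.weighted_scan(Xc, yt[:, t], weights)
                raw[cols, t] = ct
                beta[cols, t] = bt
            continue
        if step1.trait_type == "quantitative":
            yt = step1.loco.residuals[c]  # (N, T)
            num = (Xc.T @ yt.astype(Xc.dtype)).astype(np.float64)
            xx = np.einsum("ij,ij->j", Xc, Xc, dtype=np.float64)[:, None]
            # per-chromosome variance normalization: LOCO residuals on
            # chromosomes that carry signal retain their own genetic
            # variance, so a single genome-wide constant would over-shrink
            # statistics on signal-free chromosomes
            denom = xx * yt.var(axis=0)[None, :]
        else:
            phat = step1.loco.phat[c]
            w = step1.loco.weights[c]
            resid = (step1.y_raw - phat).astype(Xc.dtype)
            num = (Xc.T @ resid).astype(np.float64)
            xx = np.stack(
                [
                    np.einsum("ij,i,ij->j", Xc, w[:, t].astype(Xc.dtype), Xc,
                              dtype=np.float64)
                    for t in range(t_count)
                ],
                axis=1,
            )
            denom = xx
        with np.errstate(divide="ignore", invalid="ignore"):
            raw[cols] = np.where(denom > 0, num**2 / denom, np.nan)
            beta[cols] = np.where(xx > 0, num / xx, np.nan)

    results = {}
    mafs = np.array([G.variants[j].maf for j in X.retained])
    f_a1 = np.array(
        [
            _a1_frequency(G, j)
            for j in X.retained
        ]
    )
    for t, name in enumerate(traits):
        if step1.trait_type == "quantitative":
            y_sub = step1.y_adj[subset, t]
            y_sub = residualize_covariates(y_sub, C_sub)
            if weights is not None:
                _, _, ref = assoc.weighted_scan(Xsub_adj, y_sub,
                                                weights[subset])
            else:
                ref = assoc.linear_reference_chisq(Xsub_adj, y_sub)
            gain = float(step1.loco.neff_gain[t])
        else:
            y_sub = step1.y_raw[subset, t]
            ref = assoc.logistic_reference_chisq(Xsub_adj, y_sub, C_sub)
            gain = 1.0
        cal = assoc.calibrate(raw[calib, t], ref, neff_gain=gain,
                              relatedness_adjustment=rel_adj)
        chisq = cal.gamma * raw[:, t]
        log10p = assoc.chisq_to_log10p(chisq)
        with np.errstate(divide="ignore", invalid="ignore"):
            pvals = np.power(10.0, -log10p)
            se = np.where(chisq > 0, np.abs(beta[:, t]) / np.sqrt(chisq), np.nan)
        df = pd.DataFrame(
            {
                "CHR": chrom_labels,
                "SNP": [G.variants[j].identifier for j in X.retained],
                "BP": [G.variants[j].position for j in X.retained],
                "A1": [G.variants[j].allele1 for j in X.retained],
                "A2": [G.variants[j].allele2 for j in X.retained],
                "A1FREQ": f_a1,
                "N": n,
                "TEST": "score",
                "BETA": beta[:, t],
                "SE": se,
                "CHISQ": chisq,
                "LOG10P": log10p,
                "P": pvals,
            }
        )
        if step1.trait_type == "binary" and firth_fallback:
            prevalence = float(step1.y_raw[:, t].mean())
            df = assoc.apply_fallback_policy(
                df,
                trait_prevalence=prevalence,
                firth_fn=_make_firth_fn(X, step1, t, chrom_labels),
            )
        results[name] = (df, cal)
    return results


def _a1_frequency(G: GenotypeMatrix, j: int) -> float:
    from .genotype_io import MISSING

    col = G.dosages[:, j]
    obs = col[col != MISSING]
    return float(obs.mean() / 2.0) if obs.size else np.nan


def _make_firth_fn(X: AdjustedMatrix, step1: Step1Result, t: int, chrom_labels):
    y = step1.y_raw[:, t]

    def firth_fn(idx):
        c = chrom_labels[idx]
        eta = logit(step1.loco.phat[c][:, t])
        x = np.asarray(X.values[:, idx], float)
        return assoc.firth_lrt(x, y, C=None, offset=eta)

    return firth_fn


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    mean_chisq_causal: float
    mean_chisq_null: float
    normalized_causal_chisq: float
    fpr: dict
    n_causal: int
    n_null: int


def evaluate(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    causal_col: str,
    thresholds=(5e-2, 1e-3, 1e-5),
) -> EvaluationReport:
    """Power/calibration summary against the simulation truth.

    Null variants are the even-chromosome ones (exact nulls under the
    odd-chromosome causal-parity design); causal variants come from the
    truth flags.  Causal means are NaN when the causal set is empty.
    """
    merged = results.merge(truth[["SNP", causal_col]], on="SNP", how="left")
    if merged[causal_col].isna().any():
        missing = merged.loc[merged[causal_col].isna(), "SNP"].tolist()[:5]
        extra = set(truth["SNP"]) - set(results["SNP"])
        raise ValueError(
            f"truth/result variant mismatch; e.g. results-only {missing}, "
            f"truth-only {sorted(extra)[:5]}"
        )
    chrom_num = merged["CHR"].astype(int)
    causal = merged[causal_col].astype(bool)
    null_mask = (chrom_num % 2 == 0) & ~causal

    null_chi = merged.loc[null_mask, "CHISQ"].to_numpy()
    causal_chi = merged.loc[causal, "CHISQ"].to_numpy()
    null_p = merged.loc[null_mask, "P"].to_numpy()

    mean_null = float(np.nanmean(null_chi)) if null_chi.size else np.nan
    mean_causal = float(np.nanmean(causal_chi)) if causal_chi.size else np.nan
    norm = mean_causal / mean_null if causal_chi.size and null_chi.size else np.nan
    fpr = {
        thr: float(np.nanmean(null_p < thr)) if null_p.size else np.nan
        for thr in thresholds
    }
    return EvaluationReport(
        mean_chisq_causal=mean_causal,
        mean_chisq_null=mean_null,
        normalized_causal_chisq=norm,
        fpr=fpr,
        n_causal=int(causal.sum()),
        n_null=int(null_mask.sum()),
    )
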