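"""QTL calling for root-angle and gravitropism traits across an IL panel.

Long-term root angle is analysed with the mixed-effect model

    trait ~ genotype + collide + (1 | germAge) + (1 | plateDate),

fit by REML with the recurrent parent as the reference level; each IL's
contrast against the reference is a putative QTL, with Benjamini–Hochberg
FDR control across the panel (default q ≤ 0.01).

Short-term gravitropism is analysed per timepoint: the fixed-effect model
``trait ~ genotype`` is fit to the swing rate at each of the 33 rate
timepoints, BH adjustment is applied over the whole genotype × timepoint
family (default q ≤ 0.05), and an IL is called a gravitropism QTL when it
differs from the reference at three or more consecutive timepoints.  Runs
are phase-labelled early (T0–T6), middle (T7–T19) or late (T20–T33) by
their midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

PHASE_WINDOWS = {"early": (0, 6), "middle": (7, 19), "late": (20, 33)}


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# mixed model for the long-term angle trait

@dataclass
class TraitModelFit:
    """Per-genotype contrasts against the reference, with FDR control."""

    effects: pd.DataFrame        # index genotype; effect, se, p, q, significant
    reference: str
    dropped_terms: tuple[str, ...] = ()

    def significant_ils(self, alpha: float | None = None) -> set[str]:
        if alpha is None:
            return set(self.effects.index[self.effects["significant"]])
        return set(self.effects.index[self.effects["q"] <= alpha])


def _genotype_effects_from_fit(params: pd.Series, bse: pd.Series, df_resid: float,
                               prefix: str) -> pd.DataFrame:
    rows = []
    for name in params.index:
        if name.startswith(prefix) and name.endswith("]"):
            geno = name[len(prefix):-1]
            beta, se = params[name], bse[name]
            tval = beta / se if se > 0 else np.inf * np.sign(beta)
            p = 2 * stats.t.sf(abs(tval), df_resid) if np.isfinite(tval) else 0.0
            rows.append((geno, beta, se, p))
    return pd.DataFrame(rows, columns=["genotype", "effect", "se", "p"]
                        ).set_index("genotype")


def fit_trait_model(records: pd.DataFrame, reference: str,
                    alpha: float = 0.01, trait_col: str = "trait") -> TraitModelFit:
    """REML fit of trait ~ genotype + collide + (1|germAge) + (1|plateDate).

    ``records`` must carry columns genotype, collide, germAge, plateDate and
    the trait.  Genotype is reference-coded against ``reference``; random
    intercepts for the two crossed factors are modelled as variance
    components.  A random factor observed at a single level is dropped (with
    a warning); if both are dropped the model reduces to OLS.  p-values use
    a t reference with residual degrees of freedom (containment-style
    approximation), and BH adjustment runs across genotypes.
    """
    if reference not in set(records["genotype"]):
        raise ValueError(f"reference genotype {reference!r} absent from records")
    if records["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    data = records.copy()
    data["collide"] = data["collide"].astype(int)

    vc = {}
    dropped = []
    for factor in ("germAge", "plateDate"):
        if data[factor].nunique() > 1:
            vc[factor] = f"0 + C({factor})"
        else:
            dropped.append(factor)
            warnings.warn(f"random factor {factor} has a single level; dropped")

    fixed = f"{trait_col} ~ C(genotype, Treatment({reference!r})) + collide"
    n_fixed = data["genotype"].nunique() + 1 + 1   # genotypes + collide + intercept
    df_resid = len(data) - n_fixed

    result = None
    if vc:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(fixed, data, groups=np.ones(len(data)),
                                    vc_formula=vc)
                result = model.fit(reml=True, method="lbfgs", maxiter=200)
            if not np.all(np.isfinite(result.bse[:n_fixed])):
                result = None
        except Exception:
            result = None
    if result is None:
        # fall back to a fixed-effect fit with the random factors as blocks
        terms = [fixed] + [f"C({f})" for f in ("germAge", "plateDate")
                           if f not in dropped and data[f].nunique() > 1]
        formula = " + ".join(terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = smf.ols(formula, data).fit()
        df_resid = result.df_resid
        if vc:
            dropped.append("mixed-fit-fallback")

    prefix = f"C(genotype, Treatment({reference!r}))[T."
    eff = _genotype_effects_from_fit(result.params, result.bse, max(df_resid, 1), prefix)
    eff["q"] = bh_adjust(eff["p"].to_numpy())
    eff["significant"] = eff["q"] <= alpha
    return TraitModelFit(eff, reference, tuple(dropped))


# ---------------------------------------------------------------------------
# per-timepoint gravitropism tests

@dataclass
class TimepointTestMatrix:
    """Genotype × timepoint grids of effects, p- and q-values."""

    effect: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    reference: str

    @property
    def timepoints(self) -> list[str]:
        return list(self.effect.columns)


def per_timepoint_tests(rates: pd.DataFrame, reference: str,
                        family: str = "global") -> TimepointTestMatrix:
    """Fit trait ~ genotype at each timepoint and contrast every genotype
    against the reference.

    ``rates`` is a wide per-root table: a ``genotype`` column plus one column
    per timepoint (T1..T33 for swing rates, T0..T33 for angles).  With two
    genotypes the per-timepoint model reduces to a two-sample t-test.  BH
    adjustment is applied over the full genotype × timepoint family
    (``family="global"``) or within each timepoint (``family="per-timepoint"``).
    """
    if family not in ("global", "per-timepoint"):
        raise ValueError("family must be 'global' or 'per-timepoint'")
    tp_cols = [c for c in rates.columns if c.startswith("T") and c[1:].isdigit()]
    genotypes = [g for g in rates["genotype"].unique() if g != reference]
    if not genotypes:
        raise ValueError("no genotypes beyond the reference")
    effect = pd.DataFrame(index=genotypes, columns=tp_cols, dtype=float)
    pmat = pd.DataFrame(index=genotypes, columns=tp_cols, dtype=float)
    groups = {g: (rates["genotype"] == g).to_numpy()
              for g in rates["genotype"].unique()}
    if any(m.sum() < 2 for m in groups.values()):
        raise ValueError("need ≥2 roots per genotype")
    n_groups = len(groups)
    for tp in tp_cols:
        y = rates[tp].to_numpy(dtype=float)
        # one-way fixed-effect model: pooled residual variance across groups
        ss, n_total = 0.0, 0
        means = {}
        for g, mask in groups.items():
            yy = y[mask]
            means[g] = yy.mean()
            ss += ((yy - means[g]) ** 2).sum()
            n_total += len(yy)
        df = n_total - n_groups
        s2 = ss / df if df > 0 else 0.0
        for geno in genotypes:
            diff = means[geno] - means[reference]
            n1, n2 = groups[geno].sum(), groups[reference].sum()
            if s2 == 0.0:
                p = 1.0 if diff == 0 else 0.0
            else:
                t = diff / np.sqrt(s2 * (1 / n1 + 1 / n2))
                p = 2 * stats.t.sf(abs(t), df)
            effect.loc[geno, tp] = diff
            pmat.loc[geno, tp] = p
    if family == "global":
        q = pd.DataFrame(bh_adjust(pmat.to_numpy().ravel()).reshape(pmat.shape),
                         index=pmat.index, columns=pmat.columns)
    else:
        q = pmat.apply(lambda col: bh_adjust(col.to_numpy()), axis=0,
                       result_type="broadcast")
    return TimepointTestMatrix(effect, pmat, q, reference)


@dataclass
class RunCall:
    """A maximal run of consecutive significant timepoints for one genotype."""

    genotype: str
    run_start: int
    run_end: int
    phase: str
    direction: str       # faster | slower than the reference

    @property
    def length(self) -> int:
        return self.run_end - self.run_start + 1


def _phase_of(midpoint: float) -> str:
    for phase, (lo, hi) in PHASE_WINDOWS.items():
        if lo <= midpoint <= hi:
            return phase
    return "late"


def consecutive_runs(matrix: TimepointTestMatrix, q_threshold: float = 0.05,
                     min_run: int = 3) -> list[RunCall]:
    """Maximal runs of ≥ ``min_run`` consecutive significant timepoints.

    The phase label comes from the run midpoint against the early/middle/late
    windows; the direction from the sign of the mean effect within the run
    (positive swing-rate effects mean a faster response than the reference).
    """
    calls: list[RunCall] = []
    tp_nums = [int(c[1:]) for c in matrix.timepoints]
    for geno in matrix.q.index:
        sig = (matrix.q.loc[geno].to_numpy() <= q_threshold)
        i = 0
        while i < len(sig):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                start_tp, end_tp = tp_nums[i], tp_nums[j]
                mean_eff = float(matrix.effect.loc[geno].to_numpy()[i:j + 1].mean())
                calls.append(RunCall(geno, start_tp, end_tp,
                                     _phase_of((start_tp + end_tp) / 2),
                                     "faster" if mean_eff > 0 else "slower"))
            i = j + 1
    return calls


# ---------------------------------------------------------------------------
# trait overlap and correlation

def trait_overlap(angle_sig: set[str], gravi_sig: set[str]) -> dict[str, set[str]]:
    """Partition QTL into angle-only, gravitropism-only, and shared sets."""
    return {"angle_only": set(angle_sig) - set(gravi_sig),
            "gravi_only": set(gravi_sig) - set(angle_sig),
            "shared": set(angle_sig) & set(gravi_sig)}


def correlate_trait_with_timepoints(avg_angles: pd.Series,
                                    rates: pd.DataFrame) -> pd.Series:
    """Squared Pearson correlation of per-genotype mean angle with the
    per-genotype mean swing rate at each timepoint.

    ``avg_angles`` is indexed by genotype; ``rates`` is genotype × timepoint.
    Timepoints where either vector is constant yield NaN.
    """
    common = avg_angles.index.intersection(rates.index)
    if len(common) < 3:
        raise ValueError("need at least 3 genotypes")
    a = avg_angles.loc[common].to_numpy(dtype=float)
    out = {}
    for tp in rates.columns:
        r = rates.loc[common, tp].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(r) == 0:
            out[tp] = np.nan
        else:
            out[tp] = float(np.corrcoef(a, r)[0, 1] ** 2)
    return pd.Series(out, name="R2")


def fixed_model_plate(data: pd.DataFrame, trait_col: str = "angle") -> pd.DataFrame:
    """Two-way fixed-effect ANOVA of angle ~ 1 + genotype * plate.

    ``data`` needs columns genotype (two levels: line and control), plate,
    and the trait.  Both genotypes must appear on both plates.  Returns the
    sequential ANOVA table (rows genotype, plate, interaction, residual).
    """
    cells = data.groupby(["genotype", "plate"]).size()
    if len(cells) < data["genotype"].nunique() * data["plate"].nunique():
        raise ValueError("every genotype × plate cell must be populated")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(f"{trait_col} ~ C(genotype) * C(plate)", data).fit()
        table = sm.stats.anova_lm(fit, typ=1)
    return table
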