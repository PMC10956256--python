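"""Cross-validation, predictive ability and paired-sample comparison.

Two splitting schemes are supported: repeated random 9:1 train/test
partitions (Monte Carlo cross-validation on real data) and a random split
into five even parts with four used for training (the simulation protocol).
Predictive ability is the Pearson correlation between predictions and
held-out phenotypes; because every method is evaluated on exactly the same
replicate splits, methods are compared with a paired-sample t-test over
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import (
    BasePredictionSet,
    SwarmConfig,
    select_reference_method,
    train_elpgv,
)
from .learners import ChainConfig, GenotypeMatrix, PhenotypeTable, build_grm, fit_method
from .simulate import SimulationDesign, simulate_trait

__all__ = [
    "SplitPlan",
    "ComparisonResult",
    "make_splits",
    "predictive_ability",
    "paired_t_test",
    "run_benchmark",
    "run_simulation_study",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("BayesA", "BayesB", "BayesCpi", "GBLUP")
ENSEMBLE_NAME = "ELPGV"


@dataclass(frozen=True)
class SplitPlan:
    """One train/test partition of the individuals."""

    replicate: int
    train: np.ndarray
    test: np.ndarray
    scheme: str


def make_splits(
    ids,
    scheme: str,
    n_replicates: int,
    rng: np.random.Generator,
) -> list[SplitPlan]:
    """Independent random partitions, one per replicate.

    ``ratio_9_1`` holds out round(n/10) individuals; ``parts_5_hold_1``
    shuffles, cuts into five near-even parts and holds one part out.
    """
    ids = np.asarray(ids)
    n = len(ids)
    plans: list[SplitPlan] = []
    if scheme == "ratio_9_1":
        if n < 10:
            raise ValueError("9:1 splitting needs at least 10 individuals")
        n_test = int(round(n / 10))
        for r in range(n_replicates):
            perm = rng.permutation(n)
            plans.append(
                SplitPlan(r, np.sort(perm[n_test:]), np.sort(perm[:n_test]), scheme)
            )
    elif scheme == "parts_5_hold_1":
        if n < 5:
            raise ValueError("5-part splitting needs at least 5 individuals")
        for r in range(n_replicates):
            perm = rng.permutation(n)
            parts = np.array_split(perm, 5)
            held = int(rng.integers(5))
            test = parts[held]
            train = np.concatenate([p for j, p in enumerate(parts) if j != held])
            plans.append(SplitPlan(r, np.sort(train), np.sort(test), scheme))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return plans


def predictive_ability(predicted, observed) -> float:
    """Pearson correlation between predictions and observations; constant
    input is an error rather than a silent zero."""
    x = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vectors must be aligned")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("predictive ability undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def paired_t_test(
    abilities_a, abilities_b, alternative: str = "two-sided"
) -> tuple[float, int, float]:
    """Paired-sample t-test on per-replicate abilities.

    ``t = mean(d) / (SD(d) / sqrt(n))`` with ``d = a - b`` and ``n - 1``
    degrees of freedom; the p-value is two-sided by default.
    """
    a = np.asarray(abilities_a, dtype=float).ravel()
    b = np.asarray(abilities_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired replicates")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "all paired differences are identical (zero variance); the two "
            "methods are indistinguishable on these replicates"
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    if alternative == "two-sided":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    elif alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return t, df, p


@dataclass
class ComparisonResult:
    """Per-replicate abilities plus the aggregate method comparison."""

    abilities: pd.DataFrame            # replicate x method
    genetic_abilities: pd.DataFrame | None = None   # vs true genetic values
    weights: pd.DataFrame | None = None             # per-replicate averaged weights

    def summary(self, against: str = ENSEMBLE_NAME) -> pd.DataFrame:
        """Mean +/- SE per method and the paired t-test against ``against``."""
        rows = []
        ref = self.abilities[against].to_numpy()
        n = len(self.abilities)
        for method in self.abilities.columns:
            vals = self.abilities[method].to_numpy()
            se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            if method == against:
                t = df = p = np.nan
            else:
                try:
                    t, df, p = paired_t_test(ref, vals)
                except ValueError:
                    t, df, p = np.nan, n - 1, np.nan
            rows.append(
                {
                    "method": method,
                    "mean_ability": vals.mean(),
                    "se": se,
                    "t_vs_" + against.lower(): t,
                    "df": df,
                    "p_value": p,
                }
            )
        return pd.DataFrame(rows)


def _evaluate_replicate(
    genotypes: GenotypeMatrix,
    phenotypes: np.ndarray,
    plan: SplitPlan,
    methods,
    chain: ChainConfig,
    swarm: SwarmConfig,
    elpgv_mode: str,
    kinship: np.ndarray | None,
    genetic_values: np.ndarray | None,
    learner_fn=None,
):
    """Fit all base methods on the training side of one split, ensemble them,
    and score everything on the held-out side."""
    masked = np.full(len(phenotypes), np.nan)
    masked[plan.train] = phenotypes[plan.train]
    ptable = PhenotypeTable(genotypes.individual_ids, masked)

    all_preds = {}
    for method in methods:
        if learner_fn is not None:
            fit_values = learner_fn(method, genotypes, ptable, plan)
        else:
            fit = fit_method(method, genotypes, ptable, chain=chain, kinship=kinship)
            fit_values = fit.genetic_values
        all_preds[method] = np.asarray(fit_values, dtype=float)

    values = np.column_stack([all_preds[m] for m in methods])
    pred_all = BasePredictionSet(genotypes.individual_ids, list(methods), values)
    train_set = pred_all.subset(plan.train)
    test_set = pred_all.subset(plan.test)

    reference = select_reference_method(train_set, phenotypes[plan.train])
    if elpgv_mode == "reference":
        model = train_elpgv(test_set, swarm, reference_method=reference)
        elpgv_test = model.predict(test_set)
    elif elpgv_mode == "phenotype":
        model = train_elpgv(train_set, swarm, phenotypes=phenotypes[plan.train])
        elpgv_test = model.predict(test_set)
    else:
        raise ValueError(f"unknown ELPGV mode {elpgv_mode!r}")

    y_test = phenotypes[plan.test]
    row = {m: predictive_ability(values[plan.test, j], y_test)
           for j, m in enumerate(methods)}
    row[ENSEMBLE_NAME] = predictive_ability(elpgv_test, y_test)

    g_row = None
    if genetic_values is not None:
        g_test = genetic_values[plan.test]
        g_row = {m: predictive_ability(values[plan.test, j], g_test)
                 for j, m in enumerate(methods)}
        g_row[ENSEMBLE_NAME] = predictive_ability(elpgv_test, g_test)
    return row, g_row, model.averaged_weights, reference


def run_benchmark(
    genotypes: GenotypeMatrix,
    phenotypes,
    splits: list[SplitPlan],
    methods=DEFAULT_METHODS,
    chain: ChainConfig | None = None,
    swarm: SwarmConfig | None = None,
    elpgv_mode: str = "reference",
    genetic_values=None,
    learner_fn=None,
) -> ComparisonResult:
    """Run the full protocol on one dataset across pre-made splits.

    Per replicate: fit every base method with test phenotypes masked, choose
    the reference method by training fit, train the ensemble (reference mode
    by default, on the test cohort's predictions), and score predictive
    abilities on the held-out phenotypes.  ``learner_fn(method, genotypes,
    phenotype_table, plan) -> values`` may replace the real learners (e.g.
    stub predictors in tests).
    """
    chain = chain or ChainConfig()
    swarm = swarm or SwarmConfig()
    phenotypes = np.asarray(phenotypes, dtype=float).ravel()
    kinship = None
    if learner_fn is None and any(m.lower() == "gblup" for m in methods):
        kinship = build_grm(genotypes)

    rows, g_rows, weight_rows = [], [], []
    for plan in splits:
        chain_r = replace(chain, seed=chain.seed + 7919 * plan.replicate)
        swarm_r = replace(swarm, seed=swarm.seed + 7919 * plan.replicate)
        row, g_row, w, _ = _evaluate_replicate(
            genotypes, phenotypes, plan, methods, chain_r, swarm_r,
            elpgv_mode, kinship,
            np.asarray(genetic_values, dtype=float).ravel()
            if genetic_values is not None else None,
            learner_fn,
        )
        rows.append(row)
        weight_rows.append(dict(zip(methods, w)))
        if g_row is not None:
            g_rows.append(g_row)
    abilities = pd.DataFrame(rows)
    return ComparisonResult(
        abilities=abilities,
        genetic_abilities=pd.DataFrame(g_rows) if g_rows else None,
        weights=pd.DataFrame(weight_rows),
    )


def run_simulation_study(
    genotypes: GenotypeMatrix,
    design: SimulationDesign,
    n_replicates: int,
    methods=DEFAULT_METHODS,
    chain: ChainConfig | None = None,
    swarm: SwarmConfig | None = None,
    elpgv_mode: str = "reference",
    seed: int = 0,
    fresh_traits: bool = True,
) -> ComparisonResult:
    """Simulation benchmark: a fresh simulated trait per replicate (default)
    on a fixed genotype panel, each evaluated on a random 4:1 split."""
    chain = chain or ChainConfig()
    swarm = swarm or SwarmConfig()
    rng = np.random.default_rng(seed)
    kinship = build_grm(genotypes) if any(m.lower() == "gblup" for m in methods) else None

    trait = None
    rows, g_rows, weight_rows = [], [], []
    for r in range(n_replicates):
        if fresh_traits or trait is None:
            trait = simulate_trait(genotypes, design, rng)
        plan = make_splits(
            genotypes.individual_ids, "parts_5_hold_1", 1, rng
        )[0]
        plan = SplitPlan(r, plan.train, plan.test, plan.scheme)
        chain_r = replace(chain, seed=chain.seed + 7919 * r)
        swarm_r = replace(swarm, seed=swarm.seed + 7919 * r)
        row, g_row, w, _ = _evaluate_replicate(
            genotypes, trait.phenotypes, plan, methods, chain_r, swarm_r,
            elpgv_mode, kinship, trait.genetic_values, None,
        )
        rows.append(row)
        g_rows.append(g_row)
        weight_rows.append(dict(zip(methods, w)))
    return ComparisonResult(
        abilities=pd.DataFrame(rows),
        genetic_abilities=pd.DataFrame(g_rows),
        weights=pd.DataFrame(weight_rows),
    )
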