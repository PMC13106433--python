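"""Replication experiments: spectral gallery and the adaptation-condition sweep.

The spectral gallery illustrates the random-matrix stability regimes of
static networks: the circular law with a mean-induced outlier, diagonal
negative feedback, Dale's-law outliers, per-row E/I balancing, unequal
population variances, and the failure of balancing under sparsity.

The stability-regulation experiment pairs 25 random sparse Dale networks
(E:I neuron ratio swept from 2:3 to 3:2) with 25 random-amplitude excitatory
step stimuli and measures, for each of four adaptation conditions (none,
SFA-only, STD-only, SFA+STD), the within-network change in the epoch-averaged
local largest Lyapunov exponent between the stimulation epoch and baseline.
Exponents are nondimensionalized by tau_d; paired differences are summarized
by their median and a two-tailed Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .connectivity import (
    NetworkSpec,
    WeightMatrix,
    balance_rows,
    generate_dale,
    generate_iid,
    diagonal_feedback,
)
from .dynamics import ModelParams
from .exceptions import AdaptnetError, ParameterError, UndefinedTestError
from .lyapunov import DEFAULT_TRANSIENT, benettin_network
from .spectra import (
    EigenSpectrum,
    circular_law_radius,
    count_outliers,
    eigenvalues,
)
from .stimuli import StimulusSpec, random_step

__all__ = [
    "CONDITIONS",
    "ConditionResult",
    "ExperimentTable",
    "run_condition",
    "run_sweep",
    "wilcoxon_signed_rank",
    "run_spectral_gallery",
    "GalleryConfig",
]

#: condition name -> (sfa_enabled, std_enabled)
CONDITIONS: Dict[str, Tuple[bool, bool]] = {
    "none": (False, False),
    "sfa_only": (True, False),
    "std_only": (False, True),
    "sfa_std": (True, True),
}


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _signed_midranks(d: np.ndarray) -> Tuple[np.ndarray, float]:
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))  # midranks for tied magnitudes
    return ranks, float(ranks[d > 0].sum())


def _exact_two_tailed_p(ranks: np.ndarray, w_plus: float) -> float:
    # DP over the distribution of 2*W+ (doubled midranks are integers),
    # equivalent to enumerating all 2^n sign assignments.
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_two_tailed_p(ranks: np.ndarray, w_plus: float) -> float:
    from scipy.stats import norm

    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        raise UndefinedTestError("zero variance (all magnitudes tied at one value)")
    z = (w_plus - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(diffs: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (Wilcoxon's original policy) and tied magnitudes get
    midranks.  The null distribution is enumerated exactly for n <= 25;
    larger samples use the normal approximation with tie correction.

    Returns (W+, two-tailed p).
    """
    d = np.asarray(diffs, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ParameterError("differences must be finite")
    d = d[d != 0.0]
    if d.size == 0:
        raise UndefinedTestError("all differences are zero")
    ranks, w_plus = _signed_midranks(d)
    if d.size <= 25:
        p = _exact_two_tailed_p(ranks, w_plus)
    else:
        p = _normal_two_tailed_p(ranks, w_plus)
    return w_plus, p


# ---------------------------------------------------------------------------
# Condition runs and the paired sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepSettings:
    """Everything about one condition run except the network and stimulus."""

    dt: float = 0.01
    delta0: float = 1e-6
    renorm_interval: float = 0.1
    window: float = 1.0
    transient: float = DEFAULT_TRANSIENT
    post_duration: float = 20.0
    x0_scale: float = 0.01


@dataclass
class ConditionResult:
    network_id: int
    condition: str
    f_E: float
    lambda_stim: float  # nondimensional (lambda1_local * tau_d), stim epoch
    lambda_base: float  # nondimensional, baseline epoch
    diff: float  # lambda_stim - lambda_base
    lambda_stim_raw: float = np.nan  # 1/s
    lambda_base_raw: float = np.nan  # 1/s
    diverged: bool = False


@dataclass
class ExperimentTable:
    rows: List[ConditionResult]
    summary: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def diffs(self, condition: str) -> np.ndarray:
        return np.array(
            [r.diff for r in self.rows
             if r.condition == condition and not r.diverged]
        )

    def summarize(self, bootstrap: int = 2000, seed: int = 0) -> None:
        """Per-condition median difference, signed-rank test, bootstrap CI."""
        rng = np.random.default_rng(seed)
        self.summary = {}
        for cond in dict.fromkeys(r.condition for r in self.rows):
            d = self.diffs(cond)
            stat, p = wilcoxon_signed_rank(d)
            meds = np.median(
                rng.choice(d, size=(bootstrap, d.size), replace=True), axis=1
            )
            lo, hi = np.percentile(meds, [2.5, 97.5])
            self.summary[cond] = {
                "n": int(d.size),
                "median_diff": float(np.median(d)),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "wilcoxon_statistic": float(stat),
                "p_value": float(p),
                "n_diverged": int(
                    sum(r.condition == cond and r.diverged for r in self.rows)
                ),
            }


def run_condition(
    W: WeightMatrix,
    stim: StimulusSpec,
    condition: str,
    p: ModelParams,
    settings: Optional[SweepSettings] = None,
    seed: int = 0,
    network_id: int = 0,
    f_E: Optional[float] = None,
) -> ConditionResult:
    """Simulate baseline/stim/post epochs under one adaptation condition and
    return the paired stim-minus-baseline change of the local exponent.

    The same (W, stim, seed) must be reused across conditions for pairing;
    the initial state and perturbation direction consume identical RNG draws
    regardless of the adaptation flags.
    """
    if condition not in CONDITIONS:
        raise ParameterError(
            f"unknown condition {condition!r}; expected one of {list(CONDITIONS)}"
        )
    settings = settings or SweepSettings()
    sfa, std = CONDITIONS[condition]
    p_cond = p.with_condition(sfa, std)
    T = stim.t_off + settings.post_duration
    if f_E is None:
        f_E = float(np.mean(W.is_excitatory))
    try:
        trace = benettin_network(
            W,
            p_cond,
            stim,
            T=T,
            dt=settings.dt,
            delta0=settings.delta0,
            renorm_interval=settings.renorm_interval,
            window=settings.window,
            seed=seed,
            x0_scale=settings.x0_scale,
        )
    except AdaptnetError:
        return ConditionResult(
            network_id, condition, f_E, np.nan, np.nan, np.nan, diverged=True
        )
    base_raw = trace.mean_over(0.0, stim.t_on, settings.transient)
    stim_raw = trace.mean_over(stim.t_on, stim.t_off, settings.transient)
    base_nd = base_raw * p.tau_d
    stim_nd = stim_raw * p.tau_d
    return ConditionResult(
        network_id,
        condition,
        f_E,
        stim_nd,
        base_nd,
        stim_nd - base_nd,
        stim_raw,
        base_raw,
    )


def run_sweep(
    n_networks: int = 25,
    f_E_range: Tuple[float, float] = (0.4, 0.6),
    conditions: Sequence[str] = tuple(CONDITIONS),
    base_spec: Optional[NetworkSpec] = None,
    params: Optional[ModelParams] = None,
    settings: Optional[SweepSettings] = None,
    amp_max: float = 0.5,
    t_on: float = 20.0,
    t_off: float = 40.0,
    master_seed: int = 0,
) -> ExperimentTable:
    """The paired E:I sweep: one fresh (network, stimulus) pair per f_E value,
    all conditions run on each pair.

    Network i gets f_E linearly spaced over ``f_E_range``, a fresh Dale
    matrix and a fresh stimulus, all seeded from ``master_seed``; the four
    conditions share them exactly.
    """
    if n_networks < 5:
        raise ParameterError(f"need n_networks >= 5, got {n_networks}")
    for cond in conditions:
        if cond not in CONDITIONS:
            raise ParameterError(f"unknown condition {cond!r}")
    base_spec = base_spec or NetworkSpec()
    params = params or ModelParams()
    settings = settings or SweepSettings()
    seed_rng = np.random.default_rng(master_seed)
    seeds = seed_rng.integers(0, 2**31, size=(n_networks, 3))
    f_Es = np.linspace(f_E_range[0], f_E_range[1], n_networks)
    rows: List[ConditionResult] = []
    for i, f_E in enumerate(f_Es):
        spec = replace(base_spec, f_E=float(f_E), seed=int(seeds[i, 0]))
        W = generate_dale(spec)
        stim = random_step(
            spec.N, W.labels, t_on, t_off, amp_max, seed=int(seeds[i, 1])
        )
        for cond in conditions:
            rows.append(
                run_condition(
                    W,
                    stim,
                    cond,
                    params,
                    settings,
                    seed=int(seeds[i, 2]),
                    network_id=i,
                    f_E=float(f_E),
                )
            )
    table = ExperimentTable(rows)
    table.summarize(seed=int(seed_rng.integers(0, 2**31)))
    return table


# ---------------------------------------------------------------------------
# Spectral gallery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GalleryConfig:
    """Illustration parameters for the six spectral-regime scenarios.

    Values are chosen to place each panel squarely in its regime (the
    ensembles are otherwise generic): sigma sets the bulk radius to 1 for a
    dense N=1000 matrix; the i.i.d. mean puts its outlier at 2.5; Dale means
    are 5 bulk-entry standard deviations so the Dale outliers clear the disk.
    """

    N: int = 1000
    sigma: float = 1.0 / np.sqrt(1000.0)
    iid_mu: float = 2.5 / 1000.0
    feedback_margin: float = 1.05  # g = margin * bulk radius in scenario B
    dale_mu: float = 5.0 / np.sqrt(1000.0)
    sigma_ratio_EI: float = 2.0  # scenario E: sigma_E / sigma_I
    sparse_d: float = 0.5  # scenario F
    f_E: float = 0.5


@dataclass
class GalleryScenario:
    name: str
    description: str
    spectrum: EigenSpectrum
    radius: float
    n_outliers: int
    outliers: np.ndarray


def run_spectral_gallery(
    config: Optional[GalleryConfig] = None, seed: int = 0
) -> Dict[str, GalleryScenario]:
    """Six eigenspectra spanning the static-stability regimes (A-F).

    A: i.i.d. with slightly positive mean -> circular bulk + one real outlier.
    B: zero-mean i.i.d. with diagonal negative feedback -> bulk shifted to
       the edge of stability.
    C: dense Dale's law, zero network-average weight -> outliers despite the
       zero mean.
    D: the same matrix with per-row E/I balancing -> outliers suppressed.
    E: unequal population standard deviations -> spectrum concentrated
       toward the center.
    F: sparse (d = 0.5) Dale's law, row-balanced -> outliers persist;
       balancing no longer constrains them.
    """
    cfg = config or GalleryConfig()
    N, s = cfg.N, cfg.sigma
    out: Dict[str, GalleryScenario] = {}

    R_dense = circular_law_radius(s, N, 1.0)
    W_a = generate_iid(N, mu=cfg.iid_mu, sigma=s, d=1.0, seed=seed)
    spec_a = eigenvalues(W_a, predicted_radius=R_dense)
    n_out, outs = count_outliers(spec_a, R_dense)
    out["A"] = GalleryScenario(
        "A", "iid, positive mean: bulk disk plus a real outlier near mu*N",
        spec_a, R_dense, n_out, outs,
    )

    W_b0 = generate_iid(N, mu=0.0, sigma=s, d=1.0, seed=seed + 1)
    g = cfg.feedback_margin * R_dense
    W_b = diagonal_feedback(W_b0, g)
    spec_b = eigenvalues(W_b, predicted_radius=R_dense)
    n_out, outs = count_outliers(spec_b.shifted(g), R_dense)
    out["B"] = GalleryScenario(
        "B", f"diagonal feedback g = {g:.3f} shifts the bulk to the stable side",
        spec_b, R_dense, n_out, outs,
    )

    dale = NetworkSpec(
        N=N, f_E=cfg.f_E, d=1.0, mu_E=cfg.dale_mu, mu_I_mag=cfg.dale_mu,
        sigma_E=s, sigma_I=s, seed=seed + 2,
    )
    W_c = generate_dale(dale)
    spec_c = eigenvalues(W_c, predicted_radius=R_dense)
    n_out, outs = count_outliers(spec_c, R_dense)
    out["C"] = GalleryScenario(
        "C", "dense Dale's law, zero net mean: outliers from E/I structure",
        spec_c, R_dense, n_out, outs,
    )

    W_d = balance_rows(W_c)
    spec_d = eigenvalues(W_d, predicted_radius=R_dense)
    n_out, outs = count_outliers(spec_d, R_dense, tol=0.1)
    out["D"] = GalleryScenario(
        "D", "row-balanced dense Dale's law: outliers suppressed",
        spec_d, R_dense, n_out, outs,
    )

    sig_I = s * np.sqrt(2.0 / (1.0 + cfg.sigma_ratio_EI**2))
    sig_E = cfg.sigma_ratio_EI * sig_I  # mean-square-matched to sigma
    dale_e = NetworkSpec(
        N=N, f_E=cfg.f_E, d=1.0, mu_E=cfg.dale_mu, mu_I_mag=cfg.dale_mu,
        sigma_E=sig_E, sigma_I=sig_I, seed=seed + 3,
    )
    W_e = balance_rows(generate_dale(dale_e))
    spec_e = eigenvalues(W_e, predicted_radius=R_dense)
    n_out, outs = count_outliers(spec_e, R_dense)
    out["E"] = GalleryScenario(
        "E", "unequal E/I standard deviations: spectrum concentrates centrally",
        spec_e, R_dense, n_out, outs,
    )

    R_sparse = circular_law_radius(s, N, cfg.sparse_d)
    dale_f = replace(dale, d=cfg.sparse_d, seed=seed + 4)
    W_f = balance_rows(generate_dale(dale_f))
    spec_f = eigenvalues(W_f, predicted_radius=R_sparse)
    n_out, outs = count_outliers(spec_f, R_sparse, tol=0.1)
    out["F"] = GalleryScenario(
        "F", "sparse Dale's law, row-balanced: outliers escape balancing",
        spec_f, R_sparse, n_out, outs,
    )
    return out
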