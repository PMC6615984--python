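"""Synthetic paired-omics generator, label-error injection and scoring.

The generator emulates the study conditions used to characterize the
matchers: Type A profiles are iid standard normal; each Type B cis
feature is Y = r/sqrt(1-r^2) * X + eps with eps standard normal, so
that corr(X, Y) = r exactly.  Planted cis features draw |r| from a
half-normal truncated below at the correlation that reaches the BH
significance boundary; a further 2,000 "null" features draw r from a
centered normal, so the candidate list mixes strong, weak and absent
signal.  Ten percent extra unmatched samples per type mimic the
unbalanced sample lists of real paired datasets, and label errors are
planted by deranging a chosen fraction of Type B sample labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .align import iterate_alignment
from .cis import CisCandidateMap
from .core import OmicsMatrix
from .results import AlignmentResult

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "AlignmentMetrics",
    "significance_threshold_r",
    "simulate_dataset",
    "inject_label_errors",
    "evaluate_alignment",
    "run_grid",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated paired dataset.

    ``n_cis`` planted significant cis pairs, ``m_samples`` matched core
    samples, ``n_null`` extra candidate pairs with random effect sizes,
    ``extra_fraction`` unmatched samples appended per type.  ``r_scale``
    is the scale of the half-normal the planted |r| are drawn from
    (truncated below at the significance threshold); ``r_null_scale``
    is the scale of the centered normal for null pairs, small so that
    null pairs rarely pass the significance threshold and the planted
    count ``n_cis`` is the realized number of significant
    cis-associations — the quantity the study conditions sweep.
    """

    n_cis: int = 500
    m_samples: int = 200
    n_null: int = 2000
    error_rate: float = 0.0
    extra_fraction: float = 0.10
    seed: int = 0
    r_scale: float = 0.3
    r_null_scale: float = 0.03
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.n_cis < 1:
            raise ValueError("n_cis must be >= 1")
        if self.m_samples < 3:
            raise ValueError("m_samples must be >= 3")


@dataclass
class SimulatedDataset:
    """Paired matrices with known truth.

    ``true_pairing`` maps each core Type A sample ID to the Type B
    label whose column carries the same individual's data.
    ``injected_errors`` records the applied label permutation
    (individual -> new label).
    """

    matA: OmicsMatrix
    matB: OmicsMatrix
    candidates: CisCandidateMap
    true_pairing: dict[str, str]
    planted_r: np.ndarray
    null_r: np.ndarray
    injected_errors: dict[str, str] = field(default_factory=dict)
    config: SimulationConfig | None = None

    @property
    def core_samples(self) -> list[str]:
        return sorted(self.true_pairing)


def significance_threshold_r(M: int, n_true: int, n_null: int, alpha: float = 0.05) -> float:
    """Correlation reaching the BH significance boundary at sample size M.

    Assuming the ``n_true`` planted pairs occupy the top ranks, the BH
    step-up boundary for the last of them is ``alpha * n_true /
    (n_true + n_null)``; the returned r is where the two-sided p of the
    t-approximation (df = M - 2) equals that boundary.  Monotone
    decreasing in M.
    """
    if M < 4:
        raise ValueError("M must be >= 4")
    p_bound = alpha * n_true / (n_true + n_null)
    df = M - 2
    t_star = stats.t.ppf(1.0 - p_bound / 2.0, df)
    r = t_star / math.sqrt(df + t_star**2)
    if not 0.0 < r < 1.0:
        raise ValueError("no admissible correlation threshold in (0, 1)")
    return float(r)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one paired dataset under the configured study conditions."""
    M = cfg.m_samples
    r_cut = significance_threshold_r(M, cfg.n_cis, cfg.n_null, cfg.alpha)
    if r_cut >= 0.99:
        raise ValueError("significance threshold >= 0.99: no admissible effect sizes")

    rng_r = _rng(cfg.seed, 0)
    rng_x = _rng(cfg.seed, 1)
    rng_e = _rng(cfg.seed, 2)

    # effect sizes: planted |r| half-normal truncated to [r_cut, 0.99], random sign
    a, b = r_cut / cfg.r_scale, 0.99 / cfg.r_scale
    mag = stats.truncnorm.rvs(a, b, loc=0.0, scale=cfg.r_scale, size=cfg.n_cis, random_state=rng_r)
    sign = rng_r.choice([-1.0, 1.0], size=cfg.n_cis)
    planted_r = mag * sign
    if cfg.r_null_scale > 0:
        null_r = np.clip(rng_r.normal(0.0, cfg.r_null_scale, size=cfg.n_null), -0.989, 0.989)
    else:
        null_r = np.zeros(cfg.n_null)
    r_all = np.concatenate([planted_r, null_r])
    n_feat = r_all.size

    n_extra = math.floor(cfg.extra_fraction * M)
    core = [f"P{k:04d}" for k in range(1, M + 1)]
    extraA = [f"XA{k:03d}" for k in range(1, n_extra + 1)]
    extraB = [f"XB{k:03d}" for k in range(1, n_extra + 1)]

    n_ind = M + 2 * n_extra
    X = rng_x.standard_normal((n_feat, n_ind))
    eps = rng_e.standard_normal((n_feat, n_ind))
    slope = (r_all / np.sqrt(1.0 - r_all**2))[:, None]
    Y = slope * X + eps

    idxA = list(range(M)) + list(range(M, M + n_extra))
    idxB = list(range(M)) + list(range(M + n_extra, M + 2 * n_extra))
    featA = [f"fa{k:04d}" for k in range(1, n_feat + 1)]
    featB = [f"fb{k:04d}" for k in range(1, n_feat + 1)]
    matA = OmicsMatrix(X[:, idxA], featA, core + extraA, "typeA")
    matB = OmicsMatrix(Y[:, idxB], featB, core + extraB, "typeB")
    candidates = CisCandidateMap(list(zip(featA, featB)), provenance="explicit")
    true_pairing = {s: s for s in core}
    return SimulatedDataset(
        matA=matA,
        matB=matB,
        candidates=candidates,
        true_pairing=true_pairing,
        planted_r=planted_r,
        null_r=null_r,
        config=cfg,
    )


def _derangement(k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random derangement of range(k) by rejection."""
    while True:
        perm = rng.permutation(k)
        if not np.any(perm == np.arange(k)):
            return perm


def _swap_permutation(k: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed-point-free involution of range(k) (k even): disjoint 2-cycles."""
    order = rng.permutation(k)
    perm = np.empty(k, dtype=int)
    for t in range(0, k, 2):
        perm[order[t]] = order[t + 1]
        perm[order[t + 1]] = order[t]
    return perm


def inject_label_errors(d: SimulatedDataset, rate: float, seed: int = 0, kind: str = "derangement") -> SimulatedDataset:
    """Plant label errors by permuting a fraction of Type B core labels.

    ``round(rate * M)`` core samples are selected and their labels
    permuted with no fixed point, so the realized error rate equals the
    nominal one exactly.  ``kind="swap"`` restricts the permutation to
    disjoint 2-cycles (reciprocal swaps; the count is rounded down to
    even).  Returns a new dataset; the input is untouched.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    core = sorted(d.true_pairing)
    M = len(core)
    k = round(rate * M)
    if kind == "swap":
        k -= k % 2
    if k == 0:
        return replace(d, matB=d.matB.copy(), injected_errors={}, true_pairing=dict(d.true_pairing))
    if k < 2:
        raise ValueError("cannot derange fewer than 2 labels; raise the rate or sample size")
    rng = _rng(seed, 3)
    sel = sorted(rng.choice(M, size=k, replace=False))
    labels = [core[i] for i in sel]
    perm = _derangement(k, rng) if kind == "derangement" else _swap_permutation(k, rng)

    matB = d.matB.copy()
    pos = {s: matB.sample_index(s) for s in labels}
    old_values = matB.values[:, [pos[s] for s in labels]].copy()
    injected: dict[str, str] = {}
    true_pairing = dict(d.true_pairing)
    for t, s in enumerate(labels):
        new_label = labels[perm[t]]
        # data of individual s now sits under new_label
        matB.values[:, pos[new_label]] = old_values[:, t]
        injected[s] = new_label
        true_pairing[s] = new_label
    return replace(d, matB=matB, injected_errors=injected, true_pairing=true_pairing)


@dataclass
class AlignmentMetrics:
    sensitivity: float
    precision: float
    fpr: float
    f_measure: float
    n_truly_aligned: int
    n_aligned: int
    n_simulated: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "fpr": self.fpr,
            "f_measure": self.f_measure,
            "n_truly_aligned": self.n_truly_aligned,
            "n_aligned": self.n_aligned,
            "n_simulated": self.n_simulated,
        }


def evaluate_alignment(result: AlignmentResult, truth: dict[str, str]) -> AlignmentMetrics:
    """Score an alignment against the known pairing.

    Sensitivity (recall) = truly aligned / simulated pairs; precision
    (specificity in this setting) = truly aligned / aligned; FPR = 1 -
    precision; F = 2 * precision * recall / (precision + recall),
    reported as 0 when both are 0.  An aligned pair is truly aligned
    iff its partner matches the truth, whether self or cross.
    """
    aligned = result.aligned_pairs()
    n_aligned = len(aligned)
    n_true = sum(1 for a, b in aligned if truth.get(a) == b)
    n_sim = len(truth)
    sens = n_true / n_sim if n_sim else 0.0
    prec = n_true / n_aligned if n_aligned else 0.0
    f = 2 * prec * sens / (prec + sens) if (prec + sens) > 0 else 0.0
    return AlignmentMetrics(
        sensitivity=sens,
        precision=prec,
        fpr=1.0 - prec if n_aligned else 0.0,
        f_measure=f,
        n_truly_aligned=n_true,
        n_aligned=n_aligned,
        n_simulated=n_sim,
    )


def _cell_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(
    n_list,
    m_list,
    error_rates,
    reps: int = 1,
    seed: int = 0,
    methods=("probabilistic", "rank"),
    max_iter: int = 20,
    sim_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Sweep the (N_cis, M, error rate) grid with both matchers.

    Each cell simulates a dataset, injects label errors, runs the full
    iterative alignment and scores it against the truth.  Per-cell
    failures are recorded (``status="failed"``) and the sweep
    continues.  Fully reproducible from ``seed``.
    """
    if not (len(n_list) and len(m_list) and len(error_rates)):
        raise ValueError("grid axes must be non-empty")
    sim_kwargs = sim_kwargs or {}
    rows = []
    for iN, n_cis in enumerate(n_list):
        for iM, m in enumerate(m_list):
            for iR, rate in enumerate(error_rates):
                for rep in range(reps):
                    cell_seed = _cell_seed(seed, iN, iM, iR, rep)
                    try:
                        cfg = SimulationConfig(
                            n_cis=n_cis, m_samples=m, error_rate=rate, seed=cell_seed, **sim_kwargs
                        )
                        data = simulate_dataset(cfg)
                        data = inject_label_errors(data, rate, seed=cell_seed)
                    except Exception as exc:  # noqa: BLE001 - per-cell isolation
                        for method in methods:
                            rows.append(_failed_row(method, n_cis, m, rate, rep, str(exc)))
                        continue
                    for method in methods:
                        try:
                            out = iterate_alignment(
                                data.matA,
                                data.matB,
                                data.candidates,
                                matcher=method,
                                max_iter=max_iter,
                                seed=cell_seed,
                            )
                            metrics = evaluate_alignment(out.result, data.true_pairing)
                            rows.append(
                                {
                                    "method": method,
                                    "n_cis": n_cis,
                                    "m_samples": m,
                                    "error_rate": rate,
                                    "rep": rep,
                                    "status": "ok",
                                    "converged": out.converged,
                                    "n_iterations": out.n_iterations,
                                    "n_cis_significant": out.cis.n_significant,
                                    **metrics.as_dict(),
                                }
                            )
                        except Exception as exc:  # noqa: BLE001
                            rows.append(_failed_row(method, n_cis, m, rate, rep, str(exc)))
    return pd.DataFrame(rows)


def _failed_row(method, n_cis, m, rate, rep, message) -> dict:
    return {
        "method": method,
        "n_cis": n_cis,
        "m_samples": m,
        "error_rate": rate,
        "rep": rep,
        "status": "failed",
        "converged": False,
        "n_iterations": 0,
        "n_cis_significant": 0,
        "sensitivity": np.nan,
        "precision": np.nan,
        "fpr": np.nan,
        "f_measure": np.nan,
        "n_truly_aligned": 0,
        "n_aligned": 0,
        "n_simulated": 0,
        "error": message,
    }
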