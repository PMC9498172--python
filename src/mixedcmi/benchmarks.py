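"""Synthetic generators with analytic ground truths, plus benchmark harnesses.

The generators cover the simulation settings used to validate mixed-data CMI
estimators: bivariate Gaussian, uniform-on-integers with conditional uniform,
exponential with zero-inflated Poisson, their conditioned and conditionally
independent variants, multidimensional combinations (M-CMI, M-MI, M-ICMI), and
three-node causal structures (chain, fork, collider) over every qualitative /
quantitative type configuration.

Each named setting knows its analytic conditional mutual information in nats
(``ground_truth``); structure settings have no closed form and exist to
benchmark conditional-independence tests through acceptance rates.

Conventions: discrete-uniform, binomial and zero-inflated-Poisson components
are marked qualitative; Gaussian, continuous-uniform and exponential
components quantitative.  Unbounded Poisson-valued components in the structure
settings are treated as quantitative.  ``Exp(lambda)`` is the rate
parameterisation (mean ``1/lambda``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .baselines import baseline_estimate
from .cmih import cmih
from .core import MixedSample
from .permutation import TestConfig, run_test

__all__ = [
    "SETTINGS",
    "STRUCTURES",
    "GeneratedData",
    "generate",
    "generate_structure",
    "ground_truth",
    "mse_experiment",
    "acceptance_rate_experiment",
]

STRUCTURES = ("chain", "fork", "collider")


@dataclass(frozen=True)
class GeneratedData:
    """A generated sample with its X/Y/Z column blocks."""

    sample: MixedSample
    x: tuple[int, ...]
    y: tuple[int, ...]
    z: tuple[int, ...]


def _assemble(columns, qualitative, x, y, z) -> GeneratedData:
    data = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    sample = MixedSample(data, np.asarray(qualitative, dtype=bool))
    return GeneratedData(sample=sample, x=tuple(x), y=tuple(y), z=tuple(z))


def _mi_quant_cols(n, rng):
    cov = [[1.0, 0.6], [0.6, 1.0]]
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return [xy[:, 0], xy[:, 1]], [False, False]


def _mi_mixed_cols(n, rng):
    x = rng.integers(0, 5, size=n)
    y = x + rng.uniform(0.0, 2.0, size=n)
    return [x, y], [True, False]


def _mi_mixed_imbalanced_cols(n, rng):
    x = rng.exponential(1.0, size=n)
    y = np.where(rng.uniform(size=n) < 0.15, 0, rng.poisson(x))
    return [x, y], [False, True]


def _with_indep_z(cols_fn):
    def build(n, rng):
        cols, qual = cols_fn(n, rng)
        z = rng.binomial(3, 0.5, size=n)
        return _assemble(cols + [z], qual + [True], x=[0], y=[1], z=[2])

    return build


def _gen_mi(cols_fn):
    def build(n, rng):
        cols, qual = cols_fn(n, rng)
        return _assemble(cols, qual, x=[0], y=[1], z=[])

    return build


def _gen_cmi_quant_indep(n, rng):
    z = rng.binomial(9, 0.5, size=n)
    x = rng.normal(z, 1.0)
    y = rng.normal(z, 1.0)
    return _assemble([x, y, z], [False, False, True], x=[0], y=[1], z=[2])


def _gen_cmi_mixed_indep(n, rng):
    z = rng.integers(0, 5, size=n)
    x = z + rng.uniform(0.0, 2.0, size=n)
    y = rng.binomial(z, 0.5)
    return _assemble([x, y, z], [False, True, True], x=[0], y=[1], z=[2])


def _gen_cmi_mixed_imb_indep(n, rng):
    x = rng.exponential(1.0 / 10.0, size=n)  # Exp(10), rate parameterisation
    z = rng.poisson(x)
    y = rng.binomial(z + 5, 0.5)
    return _assemble([x, y, z], [False, True, True], x=[0], y=[1], z=[2])


def _gen_m_cmi(dim_z: int):
    def build(n, rng):
        cols, qual = _mi_mixed_cols(n, rng)
        for _ in range(dim_z):
            cols.append(rng.binomial(3, 0.5, size=n))
            qual.append(True)
        return _assemble(cols, qual, x=[0], y=[1], z=list(range(2, 2 + dim_z)))

    return build


def _gen_m_mi(n, rng):
    (x1, y1), q1 = _mi_quant_cols(n, rng)
    (x2, y2), q2 = _mi_mixed_cols(n, rng)
    (x3, y3), q3 = _mi_mixed_imbalanced_cols(n, rng)
    cols = [x1, x2, x3, y1, y2, y3]
    qual = [q1[0], q2[0], q3[0], q1[1], q2[1], q3[1]]
    return _assemble(cols, qual, x=[0, 1, 2], y=[3, 4, 5], z=[])


def _gen_m_icmi(n, rng):
    z1 = rng.integers(0, 5, size=n)
    z2 = rng.binomial(3, 0.5, size=n)
    z3 = rng.exponential(1.0, size=n)  # Exp(1)
    z4 = rng.exponential(1.0 / 10.0, size=n)  # Exp(10)
    x1 = rng.normal(z3, 1.0)
    x2 = rng.normal(z4, 1.0)
    x3 = rng.binomial(z1 + z2, 0.5)
    y = rng.binomial(z1 + z2, 0.5)
    cols = [x1, x2, x3, y, z1, z2, z3, z4]
    qual = [False, False, True, True, True, True, False, False]
    return _assemble(cols, qual, x=[0, 1, 2], y=[3], z=[4, 5, 6, 7])


def _truth_mi_quant() -> float:
    return -0.5 * np.log(1.0 - 0.6**2)


def _truth_mi_mixed() -> float:
    return np.log(5.0) - 4.0 * np.log(2.0) / 5.0


def _truth_mi_mixed_imbalanced(tol: float = 1e-14) -> float:
    """0.85 * (2 log 2 - gamma - sum_{k>=1} log(k) 2^{-k}), tail < 1e-8."""
    total, k = 0.0, 2  # the k = 1 term is zero
    while True:
        term = np.log(k) * 2.0**-k
        total += term
        if term < tol:
            break
        k += 1
    return 0.85 * (2.0 * np.log(2.0) - np.euler_gamma - total)


SETTINGS: dict[str, tuple[Callable, Callable | None]] = {
    "mi_quant": (_gen_mi(_mi_quant_cols), _truth_mi_quant),
    "mi_mixed": (_gen_mi(_mi_mixed_cols), _truth_mi_mixed),
    "mi_mixed_imbalanced": (_gen_mi(_mi_mixed_imbalanced_cols), _truth_mi_mixed_imbalanced),
    "cmi_quant": (_with_indep_z(_mi_quant_cols), _truth_mi_quant),
    "cmi_mixed": (_with_indep_z(_mi_mixed_cols), _truth_mi_mixed),
    "cmi_mixed_imbalanced": (_with_indep_z(_mi_mixed_imbalanced_cols), _truth_mi_mixed_imbalanced),
    "cmi_quant_indep": (_gen_cmi_quant_indep, lambda: 0.0),
    "cmi_mixed_indep": (_gen_cmi_mixed_indep, lambda: 0.0),
    "cmi_mixed_imb_indep": (_gen_cmi_mixed_imb_indep, lambda: 0.0),
    "m_mi": (
        _gen_m_mi,
        lambda: _truth_mi_quant() + _truth_mi_mixed() + _truth_mi_mixed_imbalanced(),
    ),
    "m_icmi": (_gen_m_icmi, lambda: 0.0),
}
for _d in range(0, 5):
    SETTINGS[f"m_cmi_{_d}"] = (_gen_m_cmi(_d), _truth_mi_mixed)


def generate(setting: str, n: int, seed=None, rng: np.random.Generator | None = None, **kwargs) -> GeneratedData:
    """Draw n i.i.d. rows from a named setting (reproducible given a seed)."""
    if setting in STRUCTURES:
        config_string = kwargs.pop("config_string", None)
        if config_string is None:
            raise ValueError("structure settings need a config_string, e.g. 'ttl'")
        return generate_structure(setting, config_string, n, seed=seed, rng=rng)
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    builder, _ = SETTINGS[setting]
    return builder(n, rng)


def ground_truth(setting: str, **kwargs) -> float:
    """Analytic CMI (nats) of a named setting; structure settings have none."""
    if setting in STRUCTURES:
        raise ValueError(f"{setting!r} is a structure setting with unknown ground truth")
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}")
    _, truth = SETTINGS[setting]
    return float(truth())


# ---------------------------------------------------------------------------
# Three-node causal structures over type configurations
#
# Roots: quantitative ~ N(0,1); qualitative ~ uniform on {0..3}.  Edges:
# quant->quant adds unit Gaussian noise to the parent; quant->qual draws
# Bi(3, expit(2 * parent)); qual->quant uses the category code as a Gaussian
# mean; qual->qual copies the parent with a 10% uniform relabel.  A collider
# child combines both parents additively (centred) before the same rules.
# ---------------------------------------------------------------------------

_N_CAT = 4  # qualitative root support {0..3}


def _norm_config(config_string: str) -> str:
    config = config_string.replace("ℓ", "l").lower()
    if len(config) != 3 or any(ch not in "tl" for ch in config):
        raise ValueError(f"config string must be 3 chars over {{t, l}}, got {config_string!r}")
    return config


def _root(kind: str, n: int, rng) -> np.ndarray:
    if kind == "t":
        return rng.normal(0.0, 1.0, size=n)
    return rng.integers(0, _N_CAT, size=n).astype(float)


def _edge(parent: np.ndarray, p_kind: str, c_kind: str, n: int, rng) -> np.ndarray:
    if c_kind == "t":
        # qual parent: category-dependent means equal to the codes
        return parent + rng.normal(0.0, 1.0, size=n)
    if p_kind == "t":
        return rng.binomial(_N_CAT - 1, expit(2.0 * parent)).astype(float)
    child = parent.copy()
    relabel = rng.uniform(size=n) < 0.10
    child[relabel] = rng.integers(0, _N_CAT, size=int(relabel.sum()))
    return child


def _collider_child(sx, sy, x_kind, y_kind, c_kind, n, rng) -> np.ndarray:
    center = (1.5 if x_kind == "l" else 0.0) + (1.5 if y_kind == "l" else 0.0)
    u = sx + sy - center
    if c_kind == "t":
        return u + rng.normal(0.0, 1.0, size=n)
    return rng.binomial(_N_CAT - 1, expit(1.2 * u)).astype(float)


def generate_structure(
    structure: str, config_string: str, n: int, seed=None, rng: np.random.Generator | None = None
) -> GeneratedData:
    """Sample a chain (X->Z->Y), fork (X<-Z->Y) or collider (X->Z<-Y).

    ``config_string`` gives the types of X, Z, Y in order, e.g. ``"ttl"`` for
    quantitative X and Z, qualitative Y.  Chain and fork satisfy X indep Y | Z;
    the collider satisfies marginal independence but conditional dependence.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    cx, cz, cy = _norm_config(config_string)
    rng = rng if rng is not None else np.random.default_rng(seed)
    if structure == "chain":
        x = _root(cx, n, rng)
        z = _edge(x, cx, cz, n, rng)
        y = _edge(z, cz, cy, n, rng)
    elif structure == "fork":
        z = _root(cz, n, rng)
        x = _edge(z, cz, cx, n, rng)
        y = _edge(z, cz, cy, n, rng)
    else:
        x = _root(cx, n, rng)
        y = _root(cy, n, rng)
        z = _collider_child(x, y, cx, cy, cz, n, rng)
    qual = [cx == "l", cy == "l", cz == "l"]
    return _assemble([x, y, z], qual, x=[0], y=[1], z=[2])


# ---------------------------------------------------------------------------
# Experiment harnesses
# ---------------------------------------------------------------------------


def _estimator_handle(estimator):
    if callable(estimator):
        return estimator
    name = estimator.lower()
    if name == "cmih":
        return lambda gd: cmih(gd.sample, gd.x, gd.y, gd.z).value
    if name in ("fp", "ravk", "ms"):
        return lambda gd: baseline_estimate(gd.sample, gd.x, gd.y, gd.z, method=name)
    raise ValueError(f"unknown estimator {estimator!r}")


def mse_experiment(
    setting: str,
    n_grid: Sequence[int],
    reps: int,
    estimators: Sequence,
    seed=None,
) -> pd.DataFrame:
    """Mean squared error of estimators against the analytic ground truth.

    Generates ``reps`` independent datasets per sample size and evaluates each
    estimator on the same datasets.  Returns a tidy frame with columns
    (setting, estimator, n, mse, mean_estimate, sd_estimate, reps).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    truth = ground_truth(setting)
    names = [e if isinstance(e, str) else getattr(e, "__name__", "custom") for e in estimators]
    handles = [(_estimator_handle(e) if not callable(e) else e) for e in estimators]
    seed_seq = np.random.SeedSequence(seed)
    rows = []
    for n in n_grid:
        estimates = np.empty((len(handles), reps))
        for r, child in enumerate(seed_seq.spawn(reps)):
            gd = generate(setting, n, rng=np.random.default_rng(child))
            for e, handle in enumerate(handles):
                estimates[e, r] = handle(gd) if callable(handle) else handle
        for e, name in enumerate(names):
            est = estimates[e]
            rows.append(
                {
                    "setting": setting,
                    "estimator": name,
                    "n": n,
                    "mse": float(np.mean((est - truth) ** 2)),
                    "mean_estimate": float(est.mean()),
                    "sd_estimate": float(est.std(ddof=1)) if reps > 1 else 0.0,
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)


def acceptance_rate_experiment(
    structure: str,
    config_string: str,
    estimator="cmih",
    test: str = "locat",
    reps: int = 10,
    thresholds: Iterable[float] = (0.01, 0.05),
    n: int = 500,
    B: int = 1000,
    k_perm: int = 5,
    seed=None,
) -> dict:
    """Acceptance rates of a CI test on a causal-structure setting.

    For chain and fork (true conditional independence) the acceptance rate is
    the fraction of p-values above each threshold; for the collider (true
    conditional dependence) it is the fraction below.  Returns
    ``{"p_values": array, "rates": {threshold: rate}}``.
    """
    _norm_config(config_string)
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    seed_seq = np.random.SeedSequence(seed)
    p_values = np.empty(reps)
    for r, child in enumerate(seed_seq.spawn(reps)):
        data_rng, test_seed = np.random.default_rng(child), child.spawn(1)[0]
        gd = generate_structure(structure, config_string, n, rng=data_rng)
        config = TestConfig(
            B=B, k_perm=k_perm, scheme=test, seed=int(test_seed.generate_state(1)[0] % 2**31)
        )
        result = run_test(gd.sample, gd.x, gd.y, gd.z, estimator=estimator, config=config)
        p_values[r] = result.p_value
    rates = {}
    for thr in thresholds:
        if structure == "collider":
            rates[thr] = float(np.mean(p_values < thr))
        else:
            rates[thr] = float(np.mean(p_values > thr))
    return {"p_values": p_values, "rates": rates}
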