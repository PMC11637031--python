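"""Population optimizers over the unit hypercube: the sea-horse optimizer
(SHO), the sine-cosine algorithm (SCA), and three SHO/SCA hybrids.

All optimizers minimize a scalar objective ``f: [0,1]^Dim -> R`` with a
population of P agents over T iterations, tracking a global *elite* (the
best position ever evaluated) and recording the best-so-far fitness per
iteration, so every convergence trace is non-increasing by construction.

The sea-horse optimizer cycles three behaviors per iteration:

* **movement** — with probability ~1/2 (a standard-normal branch draw
  r1 > 0) a logarithmic-spiral step toward the elite scaled by a Lévy
  flight (Mantegna scheme, exponent λ), otherwise a Brownian drift step
  weighted by the standard-normal density;
* **predation** — a pull toward the elite that succeeds with probability
  0.9 (branch threshold 0.1) and whose step size shrinks with the
  annealing factor α = (1 − t/T)^(2t/T);
* **breeding** — the population is sorted by fitness, split into a
  "father" half and a "mother" half, and each random pair produces one
  offspring by convex recombination.  The next generation is the best P
  of the updated agents and the offspring (elitist truncation).

The SCA moves each coordinate toward the elite along a sine or cosine
wave whose amplitude b1 = a(1 − t/T) decays linearly.  The hybrids swap
one SHO phase for the SCA update:

* ``full``      movement → SCA update (replacing predation) → breeding
* ``motor``     SCA update (replacing movement) → predation → breeding
* ``breeding``  movement → predation → SCA update (no offspring)
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SHOConfig",
    "SCAConfig",
    "OptimizerResult",
    "initialize_population",
    "mantegna_sigma",
    "levy_step",
    "movement_update",
    "predation_update",
    "sca_position_update",
    "breeding_update",
    "sho_optimize",
    "sca_optimize",
    "shosca_optimize",
    "optimize",
    "ALGORITHMS",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SHOConfig:
    """Sea-horse operator constants.

    ``l`` is the Brownian drift coefficient, ``u``/``v`` the logarithmic
    spiral constants, ``s`` the Lévy step scale and ``lam`` the Lévy tail
    exponent.  ``random_lambda`` redraws λ uniformly on (0, 2] per step
    instead of keeping it fixed.  ``levy_literal`` drops the outer 1/λ
    exponent from the Mantegna σ (the less common printed variant).
    """

    l: float = 0.05
    u: float = 0.05
    v: float = 0.05
    s: float = 0.01
    lam: float = 1.5
    random_lambda: bool = False
    predation_threshold: float = 0.1
    levy_literal: bool = False

    def __post_init__(self) -> None:
        if min(self.l, self.u, self.v, self.s) <= 0:
            raise ValueError("SHO constants l, u, v, s must be positive")
        if not (0 < self.lam <= 2):
            raise ValueError(f"Levy exponent must lie in (0, 2], got {self.lam}")


@dataclass(frozen=True)
class SCAConfig:
    """Sine-cosine update constants.

    ``a`` sets the initial wave amplitude.  By default the phase b2 is drawn
    from [0, 2π] and the elite weight b3 from [0, 2] (the canonical ranges);
    ``literal_ranges`` restricts both to [0, 1].
    """

    a: float = 2.0
    literal_ranges: bool = False

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"SCA amplitude a must be positive, got {self.a}")


@dataclass
class OptimizerResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness after each iteration, length T
    evaluations: int
    elapsed: float
    seed: int | None = None
    algorithm: str = ""


def initialize_population(
    P: int, dim: int, rng: np.random.Generator, lb: float = 0.0, ub: float = 1.0
) -> np.ndarray:
    """P agents uniform on [lb, ub]^dim (default the unit hypercube)."""
    if P < 4:
        raise ValueError(f"population size must be >= 4 (breeding needs two parent groups), got {P}")
    if dim < 1:
        raise ValueError(f"dimension must be >= 1, got {dim}")
    return lb + rng.random((P, dim)) * (ub - lb)


def mantegna_sigma(lam: float, literal: bool = False) -> float:
    """Scale σ of the Mantegna Lévy-step generator.

    σ = [Γ(1+λ) sin(πλ/2) / (Γ((1+λ)/2) λ 2^((λ-1)/2))]^(1/λ); the
    ``literal`` variant omits the outer exponent.
    """
    num = math.gamma(1.0 + lam) * math.sin(math.pi * lam / 2.0)
    den = math.gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0)
    base = num / den
    return base if literal else base ** (1.0 / lam)


def levy_step(cfg: SHOConfig, rng: np.random.Generator) -> float:
    """One heavy-tailed scalar step s·(w·σ)/|K|^(1/λ), w, K ~ N(0,1)."""
    lam = cfg.lam
    if cfg.random_lambda:
        lam = max(rng.random() * 2.0, _EPS)
    sigma = mantegna_sigma(lam, literal=cfg.levy_literal)
    w = rng.standard_normal()
    K = rng.standard_normal()
    return cfg.s * (w * sigma) / max(abs(K), _EPS) ** (1.0 / lam)


def _spiral_move(
    x: np.ndarray, elite: np.ndarray, levy: float, xs: float, ys: float, zs: float
) -> np.ndarray:
    return x + levy * ((elite - x) * xs * ys * zs + elite)


def _brownian_move(
    x: np.ndarray, elite: np.ndarray, rand: float, l: float, beta: np.ndarray
) -> np.ndarray:
    return x + rand * l * beta * (x - beta * elite)


def movement_update(
    x: np.ndarray, elite: np.ndarray, cfg: SHOConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sea-horse movement: spiral (Lévy) branch if r1 ~ N(0,1) > 0, else
    Brownian drift.  θ is drawn once per call (scalar spiral geometry);
    the Brownian density weight is drawn per coordinate."""
    r1 = rng.standard_normal()
    if r1 > 0:
        theta = rng.random() * 2.0 * math.pi
        rho = cfg.u * math.exp(theta * cfg.v)
        xs, ys, zs = rho * math.cos(theta), rho * math.sin(theta), rho * theta
        lev = levy_step(cfg, rng)
        new = _spiral_move(x, elite, lev, xs, ys, zs)
    else:
        draws = rng.standard_normal(x.shape)
        beta = np.exp(-0.5 * draws**2) / math.sqrt(2.0 * math.pi)
        rand = rng.random()
        new = _brownian_move(x, elite, rand, cfg.l, beta)
    return np.clip(new, 0.0, 1.0)


def _predation_success(x_n1: np.ndarray, elite: np.ndarray, alpha: float, rand: float) -> np.ndarray:
    return alpha * ((elite - rand * x_n1) + (1.0 - alpha) * elite)


def _predation_failure(x_n1: np.ndarray, elite: np.ndarray, alpha: float, rand: float) -> np.ndarray:
    return (1.0 - alpha) * ((x_n1 - rand * elite) + alpha * x_n1)


def predation_update(
    x_n1: np.ndarray,
    elite: np.ndarray,
    t: int,
    T: int,
    cfg: SHOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predation pull toward the elite with annealing α = (1 − t/T)^(2t/T).

    A uniform draw r2 above the threshold (0.1) selects the success branch,
    so ~90% of attempts exploit around the elite; failures explore around
    the current position instead.
    """
    if T <= 0:
        raise ValueError(f"total iterations T must be positive, got {T}")
    frac = t / T
    alpha = (1.0 - frac) ** (2.0 * frac)
    r2 = rng.random()
    rand = rng.random()
    if r2 > cfg.predation_threshold:
        new = _predation_success(x_n1, elite, alpha, rand)
    else:
        new = _predation_failure(x_n1, elite, alpha, rand)
    return np.clip(new, 0.0, 1.0)


def _sca_move(
    x: np.ndarray, elite: np.ndarray, b1: float, b2: np.ndarray, b3: np.ndarray, b4: np.ndarray
) -> np.ndarray:
    sine = x + b1 * np.sin(b2) * np.abs(b3 * elite - x)
    cosine = x + b1 * np.cos(b2) * np.abs(b3 * elite - x)
    return np.where(b4 < 0.5, sine, cosine)


def sca_position_update(
    x: np.ndarray,
    elite: np.ndarray,
    t: int,
    T: int,
    cfg: SCAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sine/cosine oscillation toward the elite with decaying amplitude
    b1 = a − t·a/T; b2, b3, b4 are drawn per coordinate."""
    if T <= 0:
        raise ValueError(f"total iterations T must be positive, got {T}")
    b1 = cfg.a - t * cfg.a / T
    hi2 = 1.0 if cfg.literal_ranges else 2.0 * math.pi
    hi3 = 1.0 if cfg.literal_ranges else 2.0
    b2 = rng.random(x.shape) * hi2
    b3 = rng.random(x.shape) * hi3
    b4 = rng.random(x.shape)
    return np.clip(_sca_move(x, elite, b1, b2, b3, b4), 0.0, 1.0)


def breeding_update(
    positions: np.ndarray, fitness: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Convex recombination of fitness-sorted parent halves.

    Agents are sorted ascending by fitness; the best ⌈P/2⌉ act as fathers,
    the rest as mothers.  Each mother is paired with a distinct random
    father and the pair produces one child r3·father + (1−r3)·mother with
    a scalar r3 ~ U[0,1] per pair, giving ⌊P/2⌋ offspring.
    """
    fitness = np.asarray(fitness, dtype=np.float64)
    if np.any(~np.isfinite(fitness)):
        raise RuntimeError("breeding requires all agents to carry finite fitness")
    order = np.argsort(fitness, kind="stable")
    P = positions.shape[0]
    n_f = math.ceil(P / 2)
    fathers = positions[order[:n_f]]
    mothers = positions[order[n_f:]]
    n_m = mothers.shape[0]
    chosen = rng.permutation(n_f)[:n_m]
    r3 = rng.random(n_m)
    return r3[:, None] * fathers[chosen] + (1.0 - r3[:, None]) * mothers


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    out = np.empty(positions.shape[0])
    for k, pos in enumerate(positions):
        val = float(objective(pos))
        if not math.isfinite(val):
            raise RuntimeError(f"objective returned non-finite value {val} at position {pos}")
        out[k] = val
    return out


def _run_engine(
    objective,
    P: int,
    dim: int,
    T: int,
    update_fn,
    breed: bool,
    rng: np.random.Generator,
    init_positions: np.ndarray | None,
    seed: int | None,
    algorithm: str,
) -> OptimizerResult:
    t0 = time.perf_counter()
    if init_positions is None:
        positions = initialize_population(P, dim, rng)
    else:
        positions = np.array(init_positions, dtype=np.float64)
        if positions.shape != (P, dim):
            raise ValueError(f"init_positions must have shape {(P, dim)}")
    fitness = _evaluate(objective, positions)
    evals = P
    best = int(np.argmin(fitness))
    elite_pos = positions[best].copy()
    elite_fit = float(fitness[best])
    trace = np.empty(T)
    for t in range(T):
        median_fit = float(np.median(fitness))
        new_positions = np.empty_like(positions)
        for k in range(P):
            new_positions[k] = update_fn(positions[k], fitness[k], elite_pos, t, rng, median_fit)
        new_fitness = _evaluate(objective, new_positions)
        evals += P
        b = int(np.argmin(new_fitness))
        if new_fitness[b] < elite_fit:
            elite_fit = float(new_fitness[b])
            elite_pos = new_positions[b].copy()
        if breed:
            offspring = breeding_update(new_positions, new_fitness, rng)
            off_fitness = _evaluate(objective, offspring)
            evals += offspring.shape[0]
            pool = np.vstack([new_positions, offspring])
            pool_fit = np.concatenate([new_fitness, off_fitness])
            keep = np.argsort(pool_fit, kind="stable")[:P]
            positions, fitness = pool[keep], pool_fit[keep]
            if fitness[0] < elite_fit:
                elite_fit = float(fitness[0])
                elite_pos = positions[0].copy()
        else:
            positions, fitness = new_positions, new_fitness
        trace[t] = elite_fit
    return OptimizerResult(
        best_position=elite_pos,
        best_fitness=elite_fit,
        trace=trace,
        evaluations=evals,
        elapsed=time.perf_counter() - t0,
        seed=seed,
        algorithm=algorithm,
    )


def _as_rng(rng_or_seed) -> tuple[np.random.Generator, int | None]:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed, None
    return np.random.default_rng(rng_or_seed), rng_or_seed


def sho_optimize(
    objective,
    P: int = 10,
    dim: int = 10,
    T: int = 50,
    cfg: SHOConfig | None = None,
    rng: np.random.Generator | int | None = None,
    init_positions: np.ndarray | None = None,
) -> OptimizerResult:
    """Plain sea-horse optimizer: movement → predation → breeding."""
    cfg = cfg or SHOConfig()
    gen, seed = _as_rng(rng)

    def update(x, fit_x, elite, t, g, median_fit):
        x1 = movement_update(x, elite, cfg, g)
        return predation_update(x1, elite, t, T, cfg, g)

    return _run_engine(objective, P, dim, T, update, True, gen, init_positions, seed, "sho")


def sca_optimize(
    objective,
    P: int = 10,
    dim: int = 10,
    T: int = 50,
    cfg: SCAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    init_positions: np.ndarray | None = None,
) -> OptimizerResult:
    """Plain sine-cosine algorithm (no predation or breeding phases)."""
    cfg = cfg or SCAConfig()
    gen, seed = _as_rng(rng)

    def update(x, fit_x, elite, t, g, median_fit):
        return sca_position_update(x, elite, t, T, cfg, g)

    return _run_engine(objective, P, dim, T, update, False, gen, init_positions, seed, "sca")


def shosca_optimize(
    objective,
    P: int = 10,
    dim: int = 10,
    T: int = 50,
    sho_cfg: SHOConfig | None = None,
    sca_cfg: SCAConfig | None = None,
    variant: str = "full",
    rng: np.random.Generator | int | None = None,
    init_positions: np.ndarray | None = None,
    worst_half_only: bool = True,
) -> OptimizerResult:
    """SHO/SCA hybrid.

    ``variant='full'`` replaces predation with the SCA update,
    ``'motor'`` replaces movement, ``'breeding'`` replaces mating (the SCA
    update is applied to every agent and no offspring are produced).

    Where the SCA substitutes predation (the full variant) it acts as an
    intermediate repair step for the population's worst outcomes: by
    default only agents whose fitness falls in the worse half of the
    current population take the SCA step, while the better half keep
    their movement result — this retains good solutions between
    iterations and is what makes the hybrid converge faster than plain
    SHO.  ``worst_half_only=False`` applies the SCA step to every agent.
    """
    sho_cfg = sho_cfg or SHOConfig()
    sca_cfg = sca_cfg or SCAConfig()
    gen, seed = _as_rng(rng)
    if variant not in {"full", "motor", "breeding"}:
        raise ValueError(f"unknown SHOSCA variant {variant!r}; use full, motor or breeding")

    def sca_gate(proposed, fit_x, elite, t, g, median_fit):
        if worst_half_only and fit_x <= median_fit:
            return proposed  # better half keeps its pre-SCA position
        return sca_position_update(proposed, elite, t, T, sca_cfg, g)

    if variant == "full":

        def update(x, fit_x, elite, t, g, median_fit):
            x1 = movement_update(x, elite, sho_cfg, g)
            return sca_gate(x1, fit_x, elite, t, g, median_fit)

        breed = True
    elif variant == "motor":

        def update(x, fit_x, elite, t, g, median_fit):
            x1 = sca_position_update(x, elite, t, T, sca_cfg, g)
            return predation_update(x1, elite, t, T, sho_cfg, g)

        breed = True
    else:  # breeding: SCA replaces mating, applied to every agent

        def update(x, fit_x, elite, t, g, median_fit):
            x1 = movement_update(x, elite, sho_cfg, g)
            x2 = predation_update(x1, elite, t, T, sho_cfg, g)
            return sca_position_update(x2, elite, t, T, sca_cfg, g)

        breed = False

    name = "shosca" if variant == "full" else f"shosca-{variant}"
    return _run_engine(objective, P, dim, T, update, breed, gen, init_positions, seed, name)


ALGORITHMS = ("sho", "sca", "shosca", "shosca-motor", "shosca-breeding")


def optimize(
    algorithm: str,
    objective,
    P: int = 10,
    dim: int = 10,
    T: int = 50,
    sho_cfg: SHOConfig | None = None,
    sca_cfg: SCAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    init_positions: np.ndarray | None = None,
) -> OptimizerResult:
    """Dispatch by algorithm name (one of :data:`ALGORITHMS`)."""
    if algorithm == "sho":
        return sho_optimize(objective, P, dim, T, sho_cfg, rng, init_positions)
    if algorithm == "sca":
        return sca_optimize(objective, P, dim, T, sca_cfg, rng, init_positions)
    if algorithm in {"shosca", "shosca-motor", "shosca-breeding"}:
        variant = "full" if algorithm == "shosca" else algorithm.split("-", 1)[1]
        return shosca_optimize(
            objective, P, dim, T, sho_cfg, sca_cfg, variant, rng, init_positions
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
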