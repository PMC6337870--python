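"""Translational control analysis: dilution sweeps, substrate elasticity
and the ribosome flux control coefficient.

The elasticity quantifies the logarithmic sensitivity of the translation
rate to the ternary-complex ("substrate") concentration,

    eps_T3 = (d v_TL / d c_T3) * (c_T3 / v_TL),

and the flux control coefficient the sensitivity to ribosome ("enzyme")
levels,

    FCC = (d v_TL / d c_R) * (c_R / v_TL).

Both are estimated by central finite differences in log space over
replicate simulated rates: the substrate perturbation scales EFTu and
the whole tRNA pool jointly by (1 +/- delta) at fixed ribosomes (the
complex pool is EFTu-limited, so this perturbs the ternary-complex
level); the FCC perturbation scales ribosomes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ScenarioConfig, scale_scenario
from .rates import RateEstimate, replicate_rate
from .sequences import CodonSequence

__all__ = [
    "ControlCoefficients",
    "log_sensitivity",
    "concentration_sweep",
    "elasticity",
    "fcc",
]


@dataclass(frozen=True)
class ControlCoefficients:
    """Finite-difference control estimates at a relative concentration."""

    elasticity_T3: float | None
    fcc: float | None
    rel_conc: float
    se_elasticity: float | None = None
    se_fcc: float | None = None


def log_sensitivity(
    c_lo: float,
    v_lo: float,
    c_hi: float,
    v_hi: float,
    se_lo: float = 0.0,
    se_hi: float = 0.0,
) -> tuple[float, float]:
    """Central-difference log-log slope d ln v / d ln c with propagated SE.

    This is the shared estimator behind both coefficients; applied to an
    exact power law ``v = k c^a`` it returns ``a`` exactly.
    """
    if min(c_lo, v_lo, c_hi, v_hi) <= 0:
        raise ValueError("concentrations and rates must be positive")
    dlnc = np.log(c_hi) - np.log(c_lo)
    if dlnc == 0:
        raise ValueError("perturbed concentrations are identical")
    est = float((np.log(v_hi) - np.log(v_lo)) / dlnc)
    se = float(np.hypot(se_hi / v_hi, se_lo / v_lo) / abs(dlnc))
    return est, se


def concentration_sweep(
    base: ScenarioConfig,
    sequence: CodonSequence,
    rel_concs,
    n_seeds: int = 10,
    master_seed: int = 0,
    stop_steps: int | None = None,
) -> pd.DataFrame:
    """Replicate specific rates across a joint dilution series.

    All three pools (ribosomes, EFTu, tRNA) scale together; degenerate
    scenarios are skipped with a warning row (NaN rate).
    """
    rows = []
    for rc in rel_concs:
        try:
            cfg = scale_scenario(base, rc)
            est = replicate_rate(
                cfg, sequence, n_seeds=n_seeds, master_seed=master_seed, stop_steps=stop_steps
            )
            rows.append({"rel_conc": rc, "rate": est.rate, "se": est.se, "n_seeds": n_seeds})
        except ValueError as e:
            import warnings

            warnings.warn(f"skipping rel_conc {rc}: {e}")
            rows.append({"rel_conc": rc, "rate": np.nan, "se": np.nan, "n_seeds": 0})
    return pd.DataFrame(rows)


def _perturbed_pair(
    base: ScenarioConfig,
    sequence: CodonSequence,
    which: tuple[str, ...],
    delta: float,
    n_seeds: int,
    master_seed: int,
    stop_steps: int | None,
) -> tuple[tuple[float, RateEstimate], tuple[float, RateEstimate]]:
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    out = []
    # common random numbers across the two arms: identical replicate seeds
    # give identical ribosome placements and codon starts, so much of the
    # placement variance cancels in the central difference
    for sign in (-1, +1):
        cfg = scale_scenario(base, 1.0 + sign * delta, which=which)
        # actual (post-rounding) abundance of the perturbed pool
        if which == ("ribosomes",):
            c = cfg.machines.ribosomes
        else:
            c = min(cfg.machines.eftu, sum(cfg.trna.counts_int().values()))
        est = replicate_rate(
            cfg, sequence, n_seeds=n_seeds, master_seed=master_seed + 1,
            stop_steps=stop_steps,
        )
        out.append((float(c), est))
    return out[0], out[1]


def elasticity(
    base: ScenarioConfig,
    sequence: CodonSequence,
    delta: float = 0.10,
    n_seeds: int = 10,
    master_seed: int = 0,
    stop_steps: int | None = None,
) -> ControlCoefficients:
    """Substrate elasticity eps_T3 by central differences.

    Scales EFTu and total tRNA jointly by (1 +/- delta) holding
    ribosomes fixed; the specific rate is an adequate stand-in for v_TL
    because the ribosome count is identical in both arms.
    """
    (c_lo, lo), (c_hi, hi) = _perturbed_pair(
        base, sequence, ("eftu", "trna"), delta, n_seeds, master_seed, stop_steps
    )
    est, se = log_sensitivity(c_lo, lo.rate, c_hi, hi.rate, lo.se or 0.0, hi.se or 0.0)
    if est != 0 and se / abs(est) > 0.5:
        import warnings

        warnings.warn(f"elasticity SE/estimate ratio {se / abs(est):.2f}; increase delta or seeds")
    return ControlCoefficients(
        elasticity_T3=est, fcc=None, rel_conc=base.relative_concentration, se_elasticity=se
    )


def fcc(
    base: ScenarioConfig,
    sequence: CodonSequence,
    delta: float = 0.10,
    n_seeds: int = 10,
    master_seed: int = 0,
    stop_steps: int | None = None,
) -> ControlCoefficients:
    """Flux control coefficient of ribosomes by central differences.

    Scales the ribosome count by (1 +/- delta); the flux v_TL is the
    volume-total rate, i.e. specific rate times ribosome count.
    """
    (c_lo, lo), (c_hi, hi) = _perturbed_pair(
        base, sequence, ("ribosomes",), delta, n_seeds, master_seed, stop_steps
    )
    v_lo = lo.rate * c_lo
    v_hi = hi.rate * c_hi
    se_lo = (lo.se or 0.0) * c_lo
    se_hi = (hi.se or 0.0) * c_hi
    est, se = log_sensitivity(c_lo, v_lo, c_hi, v_hi, se_lo, se_hi)
    if est != 0 and se / abs(est) > 0.5:
        import warnings

        warnings.warn(f"FCC SE/estimate ratio {se / abs(est):.2f}; increase delta or seeds")
    return ControlCoefficients(
        elasticity_T3=None, fcc=est, rel_conc=base.relative_concentration, se_fcc=se
    )
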