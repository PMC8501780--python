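"""Counter-based random streams for scenario-comparable Monte Carlo draws.

Every stochastic outcome in the engine is a pure function of
``(seed, individual id, event, period)``.  Two projection runs sharing a seed
therefore hand the *same* uniform draw to the same individual for the same
event in the same period, regardless of which scenario is running or which
other cases happen to be in the frame.  That is the common-random-numbers
contract: scenario differences reflect assumptions, not sampling noise, and
cohorts alive in both scenarios evolve identically until an assumption
actually touches them.

The mixing function is the SplitMix64 finalizer (Steele, Lea & Flood's
``splitmix64``), applied to the xor-combined key.  It is a bijective avalanche
mixer with good equidistribution — the standard vectorisable choice when one
generator object per individual would be too slow.
"""

from __future__ import annotations

import numpy as np

_GOLD = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / (1 << 53)

# Event labels used by the engine; any small distinct integers work.
EV_MORTALITY = 1
EV_EDU_ENTRY = 2
EV_EDU_ADVANCE = 3
EV_EMIGRATION = 4
EV_FERTILITY = 5
EV_BIRTH_SEX = 6
EV_NEWBORN_SURVIVAL = 7
EV_LFP = 8


def _mix(z):
    """SplitMix64 finalizer; works on uint64 scalars and arrays."""
    z = z + _GOLD
    z = (z ^ (z >> np.uint64(30))) * _M1
    z = (z ^ (z >> np.uint64(27))) * _M2
    return z ^ (z >> np.uint64(31))


def uniforms(seed: int, ids, event: int, period: int) -> np.ndarray:
    """Uniform(0, 1) draw per id, keyed by (seed, id, event, period)."""
    ids = np.asarray(ids, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = _mix(np.uint64(seed) ^ (np.uint64(event) * _M1))
        z = _mix(z ^ (np.uint64(period) * _M2))
        h = _mix(ids ^ z)
    return (h >> np.uint64(11)).astype(np.float64) * _INV53


def child_ids(mother_ids, period: int, parity: int) -> np.ndarray:
    """Stable ids for newborns of the given mothers in the given period.

    Deterministic in (mother id, period, birth order), so the same birth event
    produces the same child id in every scenario — newborn draws then stay
    comparable across scenarios too.  The top bit is forced on to keep the
    newborn id space disjoint from baseline and immigrant ids.
    """
    mother_ids = np.asarray(mother_ids, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = _mix(np.uint64(period) * _M1 ^ np.uint64(parity) * _M2)
        h = _mix(mother_ids ^ z)
    return h | np.uint64(1 << 63)


def poisson_from_uniform(u: np.ndarray, mean: np.ndarray, kmax: int = 20) -> np.ndarray:
    """Invert the Poisson CDF at ``u`` for element-wise means.

    Gives the count ``k`` with ``F(k-1) <= u < F(k)``; capped at ``kmax``
    (means here are births per woman per 5-year step, well below 1).
    A single uniform per case keeps birth counts common-random-number
    comparable across fertility scenarios.
    """
    u = np.asarray(u, dtype=np.float64)
    mean = np.broadcast_to(np.asarray(mean, dtype=np.float64), u.shape)
    counts = np.zeros(u.shape, dtype=np.int64)
    pmf = np.exp(-mean)
    cdf = pmf.copy()
    for k in range(kmax):
        more = u >= cdf
        if not more.any():
            break
        counts[more] += 1
        pmf = pmf * mean / (k + 1)
        cdf = cdf + pmf
    return counts
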