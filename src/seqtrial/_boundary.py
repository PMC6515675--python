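"""Cached success-region boundaries for the final analysis rule.

For fixed per-arm denominators (n_C, n_T), priors and a success threshold,
the final rule "P(p_T < p_C) > threshold" holds exactly when the treatment
death count is at or below a cutoff that is non-decreasing in the control
death count.  Simulation and predictive-probability code evaluates the rule
millions of times on integer count vectors; computing the cutoff curve once
per (n_C, n_T) pair and serving lookups from it turns each evaluation into
an array index.  Curves are grown lazily over the observed control-death
range (binary search for the first point, monotone two-pointer scans for
extensions) and cached process-wide per (priors, threshold).
"""

from __future__ import annotations

import numpy as np

from .inference import BetaPosterior, _is_integer, _prob_less_closed, prob_superiority

__all__ = ["SuccessBoundary", "get_boundary"]


class SuccessBoundary:
    """Success-region oracle for one (prior_control, prior_treatment, threshold)."""

    def __init__(
        self,
        prior_control: tuple[float, float] = (1.0, 1.0),
        prior_treatment: tuple[float, float] = (1.0, 1.0),
        threshold: float = 0.975,
    ) -> None:
        self.prior_control = tuple(map(float, prior_control))
        self.prior_treatment = tuple(map(float, prior_treatment))
        self.threshold = float(threshold)
        # integer prior shapes admit the exact finite-sum evaluation without
        # going through the dispatching front end (hot path in simulation)
        if _is_integer(self.prior_control[0]):
            self._mode = "direct"
        elif _is_integer(self.prior_treatment[0]):
            self._mode = "complement"
        else:
            self._mode = "general"
        # (n_c, n_t) -> [lo_d_c, list of cutoffs for d_c = lo, lo+1, ...]
        self._curves: dict[tuple[int, int], list] = {}

    # -- exact rule on scalar counts ------------------------------------
    def prob(self, d_c: int, n_c: int, d_t: int, n_t: int) -> float:
        a0c, b0c = self.prior_control
        a0t, b0t = self.prior_treatment
        a_t, b_t = a0t + d_t, b0t + (n_t - d_t)
        a_c, b_c = a0c + d_c, b0c + (n_c - d_c)
        if self._mode == "direct":
            return _prob_less_closed(a_t, b_t, a_c, b_c)
        if self._mode == "complement":
            return 1.0 - _prob_less_closed(a_c, b_c, a_t, b_t)
        return prob_superiority(BetaPosterior(a_t, b_t), BetaPosterior(a_c, b_c)).prob_superior

    def _succ(self, d_c: int, n_c: int, d_t: int, n_t: int) -> bool:
        return self.prob(d_c, n_c, d_t, n_t) > self.threshold

    def _cutoff_scalar(self, n_c: int, n_t: int, d_c: int) -> int:
        """Largest d_t with success at (d_c, n_c, n_t); -1 if none."""
        if not self._succ(d_c, n_c, 0, n_t):
            return -1
        if self._succ(d_c, n_c, n_t, n_t):
            return n_t
        lo, hi = 0, n_t  # succ(lo) True, succ(hi) False
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if self._succ(d_c, n_c, mid, n_t):
                lo = mid
            else:
                hi = mid
        return lo

    # -- lazily grown cutoff curve --------------------------------------
    def cutoffs(self, n_c: int, n_t: int, d_lo: int, d_hi: int) -> np.ndarray:
        """Cutoff curve for d_c in [d_lo, d_hi] (inclusive)."""
        if not 0 <= d_lo <= d_hi <= n_c:
            raise ValueError("control death range outside [0, n_c]")
        key = (int(n_c), int(n_t))
        cur = self._curves.get(key)
        if cur is None:
            cur = [d_lo, [self._cutoff_scalar(n_c, n_t, d_lo)]]
            self._curves[key] = cur
        lo, vals = cur
        while lo + len(vals) - 1 < d_hi:  # extend upward
            d = lo + len(vals)
            t = vals[-1]
            while t + 1 <= n_t and self._succ(d, n_c, t + 1, n_t):
                t += 1
            vals.append(t)
        while lo > d_lo:  # extend downward
            d = lo - 1
            t = vals[0]
            while t >= 0 and not self._succ(d, n_c, t, n_t):
                t -= 1
            vals.insert(0, t)
            lo = d
        cur[0] = lo
        i0 = d_lo - lo
        return np.asarray(vals[i0 : i0 + (d_hi - d_lo + 1)], dtype=np.int64)

    def max_treatment_deaths(self, n_c: int, n_t: int, d_c: int) -> int:
        """Largest treatment death count still declared successful."""
        return int(self.cutoffs(n_c, n_t, d_c, d_c)[0])

    # -- vectorised rule -------------------------------------------------
    def success(self, d_c, n_c, d_t, n_t) -> np.ndarray:
        """Element-wise final-success indicator over integer count arrays."""
        d_c, n_c, d_t, n_t = np.broadcast_arrays(
            *(np.asarray(a, dtype=np.int64) for a in (d_c, n_c, d_t, n_t))
        )
        out = np.empty(d_c.shape, dtype=bool)
        flat_dc, flat_nc = d_c.ravel(), n_c.ravel()
        flat_dt, flat_nt = d_t.ravel(), n_t.ravel()
        flat_out = out.ravel()
        key = flat_nc * (int(flat_nt.max()) + 1 if flat_nt.size else 1) + flat_nt
        for k in np.unique(key):
            mask = key == k
            nc, nt = int(flat_nc[mask][0]), int(flat_nt[mask][0])
            dcs = flat_dc[mask]
            lo, hi = int(dcs.min()), int(dcs.max())
            curve = self.cutoffs(nc, nt, lo, hi)
            flat_out[mask] = flat_dt[mask] <= curve[dcs - lo]
        return out


_CACHE: dict[tuple, SuccessBoundary] = {}


def get_boundary(
    prior_control: tuple[float, float] = (1.0, 1.0),
    prior_treatment: tuple[float, float] = (1.0, 1.0),
    threshold: float = 0.975,
) -> SuccessBoundary:
    """Process-wide memoised :class:`SuccessBoundary`."""
    key = (
        round(float(prior_control[0]), 12),
        round(float(prior_control[1]), 12),
        round(float(prior_treatment[0]), 12),
        round(float(prior_treatment[1]), 12),
        round(float(threshold), 12),
    )
    bd = _CACHE.get(key)
    if bd is None:
        bd = SuccessBoundary(prior_control, prior_treatment, threshold)
        _CACHE[key] = bd
    return bd
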