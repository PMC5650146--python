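"""Bayesian spatially-explicit robust-design capture-recapture.

The closed portion of a robust-design model is replaced by a
spatially-explicit model: latent activity centers live on the water
cells of a habitat mask with log-linear intensity on an Island/Inshore
stratum covariate, per-secondary detection probability decays as a
half-normal in the distance from the center to the nearest surveyed
transect, and centers disperse between primary periods by a Gaussian
step truncated to water.  Population size is handled by per-primary
data augmentation with inclusion indicators; survival between primaries
is estimated by conditioning on first capture, so never-detected
augmented slots carry no survival information.

The exact likelihood of the original supplement this design follows is
not public; the functional forms here (half-normal detection, truncated
Gaussian dispersal, weakly-informative priors) are declared stand-ins,
isolated behind this module's interface.

The two parts compose as the classical two-stage robust design: the
closed portion (per-primary inclusion, centers, detection parameters,
intensity coefficient) forms a proper posterior on its own, and the
survival chain consumes the current detection parameters and centers
without feeding back into them — a deliberate cut that avoids counting
the same non-detections twice.

Sampler layout (one sweep):

1. Metropolis update of every active individual's center at every
   primary (vectorized across individuals), with entry-intensity,
   dispersal, detection and detection-location terms.
2. Direct Gibbs draw of each observed individual's death time, and
   conjugate Beta draws of the inter-primary survivals.
3. Per-primary inclusion: detected animal-periods are certain;
   observed-but-undetected periods get explicit Bernoulli inclusion
   flags; slots not yet entered are collapsed — their included count is
   Binomial after marginalizing centers over the intensity surface, and
   their cells are then Multinomial.
4. Metropolis updates of p0, sigma and the Island log-intensity
   coefficient against the closed-portion likelihood.

Per retained draw, realized marked density per stratum is the count of
included activity centers in that stratum divided by the stratum's area
inside the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .habitat import (
    HabitatMask,
    INSHORE,
    ISLAND,
    STRATUM_CODES,
    StratumAreas,
    stratum_area,
)
from .photoid import CaptureHistorySet, MarkedProportion
from .synthetic_data import effort_distance

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Augmentation size, priors, effort and MCMC controls."""

    M: int = 400
    transects: Sequence | None = None
    effort_dist: np.ndarray | None = None  # per flat mask cell, km
    n_chains: int = 3
    n_iter: int = 1000
    n_burn: int = 300
    thin: int = 1
    seed: int = 0
    sigma_move: float = 1.5  # fixed dispersal scale (km)
    sigma_prior_scale: float = 10.0  # half-normal prior on sigma
    beta_prior_sd: float = 3.0  # normal prior on the Island coefficient
    p0_init: float = 0.3
    sigma_init: float = 1.5
    fix_p0: float | None = None
    fix_sigma: float | None = None
    center_hop_km: float = 3.5
    prop_sd_logit_p0: float = 0.25
    prop_sd_log_sigma: float = 0.10
    prop_sd_beta: float = 0.4
    delta_days: np.ndarray | None = None  # interval lengths between primaries
    year_of_interval: Sequence | None = None
    report_strata: tuple = (ISLAND, INSHORE)
    rhat_warn: float = 1.1

    def __post_init__(self):
        if self.n_iter <= self.n_burn:
            raise ValueError("iterations must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.delta_days is not None and np.any(np.asarray(self.delta_days) <= 0):
            raise ValueError("delta_days must be positive")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws on the marked-animal scale."""

    density: np.ndarray  # (ndraws, P, n_report_strata) marked dolphins / km^2
    abundance_mask: np.ndarray  # (ndraws, P) realized marked animals on the mask
    p0: np.ndarray
    sigma: np.ndarray
    beta_island: np.ndarray
    phi: np.ndarray  # (ndraws, P-1)
    strata: tuple
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.density.shape[0]

    @property
    def n_primaries(self) -> int:
        return self.density.shape[1]

    def density_of(self, stratum: str) -> np.ndarray:
        return self.density[:, :, self.strata.index(stratum)]

    def to_frame(self) -> pd.DataFrame:
        recs = {}
        for j, s in enumerate(self.strata):
            for t in range(self.n_primaries):
                recs[f"D_{s}_p{t + 1}"] = self.density[:, t, j]
        recs["p0"] = self.p0
        recs["sigma"] = self.sigma
        recs["beta_island"] = self.beta_island
        for j in range(self.phi.shape[1]):
            recs[f"phi_{j + 1}"] = self.phi[:, j]
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------

def credible_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail interval by discarding the lowest and highest
    ``floor((1-level)/2 * n)`` draws and taking the extremes of the rest."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    k = int(np.floor((1.0 - level) / 2.0 * n))
    if k < 1:
        raise ValueError(
            f"too few draws ({n}) for a {level:.0%} interval; need >= {int(np.ceil(2 / (1 - level)))}"
        )
    return float(x[k]), float(x[n - k - 1])


def annualize_survival(
    phi_draws: np.ndarray,
    delta_days: np.ndarray,
    year_map: dict,
) -> pd.DataFrame:
    """Equivalent-annual survival per year.

    Per draw, each interval survival is rescaled to a 365.25-day
    exponent, ``phi ** (365.25 / delta_t)``, then the annualized values
    are averaged over the intervals assigned to each year.  Summaries
    are the posterior mean and the 95% equal-tail interval.
    """
    phi_draws = np.atleast_2d(np.asarray(phi_draws, dtype=float))
    delta_days = np.asarray(delta_days, dtype=float)
    if np.any(delta_days <= 0):
        raise ValueError("delta_days must be > 0")
    if phi_draws.shape[1] != len(delta_days):
        raise ValueError("one interval length per survival column required")
    assigned = set(year_map)
    if assigned != set(range(len(delta_days))):
        raise ValueError("every interval must be assigned to exactly one year")
    ann = phi_draws ** (DAYS_PER_YEAR / delta_days)
    rows = []
    for year in dict.fromkeys(year_map.values()):
        cols = [j for j, y in year_map.items() if y == year]
        yearly = ann[:, cols].mean(axis=1)
        lo, hi = credible_interval(yearly) if len(yearly) >= 40 else (np.nan, np.nan)
        rows.append(
            {
                "year": year,
                "n_intervals": len(cols),
                "survival": float(yearly.mean()),
                "lo95": lo,
                "hi95": hi,
            }
        )
    return pd.DataFrame(rows)


def summarize_density(
    draws: PosteriorDraws, marked_props: Sequence[MarkedProportion]
) -> pd.DataFrame:
    """Density block of the estimate table.

    Marked-scale densities are inflated per draw by 1/proportion-marked
    for the matching primary; points are posterior means, intervals are
    2.5/97.5 tail-discard intervals.  Uncertainty in the marked
    proportion itself is deliberately not propagated.
    """
    if len(marked_props) != draws.n_primaries:
        raise ValueError("one marked proportion per primary period required")
    props = np.array([mp.proportion for mp in marked_props], dtype=float)
    if np.any(props <= 0):
        raise ValueError("marked proportion must be > 0")
    rows = []
    for t in range(draws.n_primaries):
        for j, s in enumerate(draws.strata):
            marked = draws.density[:, t, j]
            total = marked / props[t]
            lo_m, hi_m = credible_interval(marked)
            lo, hi = credible_interval(total)
            rows.append(
                {
                    "primary": t + 1,
                    "stratum": s,
                    "density_marked": float(marked.mean()),
                    "density": float(total.mean()),
                    "lo95": lo,
                    "hi95": hi,
                    "lo95_marked": lo_m,
                    "hi95_marked": hi_m,
                    "inflation": float(1.0 / props[t]),
                }
            )
    return pd.DataFrame(rows)


def extrapolate_abundance(
    density_by_stratum: dict,
    areas: StratumAreas,
) -> dict:
    """Per-draw abundance: N_s = D_s * A_s, total and overall density.

    ``density_by_stratum`` maps stratum label to an array of density
    draws (any matching shapes; scalars work for arithmetic checks).
    Returns per-stratum abundance, ``total`` and ``overall_density``
    (= total / summed area).
    """
    out = {}
    total = None
    area_sum = 0.0
    for s, dens in density_by_stratum.items():
        a = areas[s]
        n_s = np.asarray(dens, dtype=float) * a
        out[s] = n_s
        total = n_s if total is None else total + n_s
        area_sum += a
    if total is None:
        raise ValueError("no strata supplied")
    out["total"] = total
    out["overall_density"] = total / area_sum
    return out


def abundance_table(
    density_block: pd.DataFrame, areas: StratumAreas, draws: PosteriorDraws,
    marked_props: Sequence[MarkedProportion],
) -> pd.DataFrame:
    """Per-primary abundance table on the total-population scale."""
    props = np.array([mp.proportion for mp in marked_props], dtype=float)
    rows = []
    for t in range(draws.n_primaries):
        dens = {
            s: draws.density[:, t, j] / props[t] for j, s in enumerate(draws.strata)
        }
        ex = extrapolate_abundance(dens, areas)
        row = {"primary": t + 1}
        for s in draws.strata:
            row[f"N_{s}"] = float(ex[s].mean())
        lo, hi = credible_interval(ex["total"])
        row.update(
            {
                "N_total": float(ex["total"].mean()),
                "lo95": lo,
                "hi95": hi,
                "overall_density": float(ex["overall_density"].mean()),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    chains = np.asarray(chains, dtype=float)
    n = chains.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    b = n * means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------

def _prepare_effort(mask: HabitatMask, config: ModelConfig) -> np.ndarray:
    if config.effort_dist is not None:
        d = np.asarray(config.effort_dist, dtype=float)
        if d.size != mask.n_cells:
            raise ValueError("effort_dist must have one entry per mask cell")
        return d
    if config.transects is None:
        raise ValueError("ModelConfig needs transects or effort_dist")
    return effort_distance(mask, config.transects)


def _snap_locations(histories: CaptureHistorySet, mask: HabitatMask) -> np.ndarray:
    """Mean detection locations with off-water points snapped to the
    nearest water cell center (with a warning)."""
    loc = histories.mean_locations.copy()
    n_snap = 0
    for i in range(loc.shape[0]):
        for t in range(loc.shape[1]):
            if np.isnan(loc[i, t, 0]):
                continue
            if not bool(mask.is_water_xy(loc[i, t, 0], loc[i, t, 1])):
                cell = mask.nearest_water_cell(loc[i, t, 0], loc[i, t, 1])
                loc[i, t] = mask.cell_centers()[cell]
                n_snap += 1
    if n_snap:
        warnings.warn(f"snapped {n_snap} off-mask detection locations to water")
    return loc


class _ChainState:
    """Mutable per-chain MCMC state (internal).

    ``s``   (n, P) center cell per observed individual and primary
    ``a``   (n,)   last primary alive (survival chain)
    ``w``   (n, P) closed-portion inclusion for undetected periods
    """

    __slots__ = ("s", "a", "w", "p0", "sigma", "beta", "psi", "phi")

    def __init__(self, s, a, w, p0, sigma, beta, psi, phi):
        self.s, self.a, self.w = s, a, w
        self.p0, self.sigma, self.beta = p0, sigma, beta
        self.psi, self.phi = psi, phi


def fit_model(
    histories: CaptureHistorySet,
    mask: HabitatMask,
    config: ModelConfig,
) -> PosteriorDraws:
    """Run the MCMC and return retained draws from all chains.

    Reproducible given ``config.seed``.  Raises if the augmentation is
    exhausted (every slot included) and warns when split-Rhat exceeds
    ``config.rhat_warn`` for any monitored scalar.
    """
    if histories.n_individuals == 0:
        raise ValueError("empty capture histories")
    n, P, K = histories.matrix.shape
    if config.M <= n:
        raise ValueError(f"augmentation size M={config.M} must exceed observed n={n}")

    # --- static structures -------------------------------------------
    wc = mask.water_cells()
    W = len(wc)
    xy = mask.cell_centers()[wc]
    strat_codes = mask.stratum_flat()[wc]
    isl = (strat_codes == STRATUM_CODES[ISLAND]).astype(float)
    d_eff = _prepare_effort(mask, config)[wc]

    report = tuple(config.report_strata)
    report_masks = [strat_codes == STRATUM_CODES[s] for s in report]
    report_areas = np.array([stratum_area(mask, s) for s in report])
    if np.any(report_areas == 0):
        missing = [s for s, a in zip(report, report_areas) if a == 0]
        raise ValueError(f"reported strata absent from mask: {missing}")

    detcount = histories.matrix.sum(axis=2).astype(float)  # (n, P)
    seen = detcount > 0
    first = seen.argmax(axis=1)
    last = P - 1 - seen[:, ::-1].argmax(axis=1)
    loc = _snap_locations(histories, mask)

    # squared distances between water cells, dispersal normalizers
    d2 = (
        (xy[:, None, 0] - xy[None, :, 0]) ** 2
        + (xy[:, None, 1] - xy[None, :, 1]) ** 2
    )
    sm2 = 2.0 * config.sigma_move**2
    logZ = np.log(np.exp(-d2 / sm2).sum(axis=1))
    logS = _LocationNormalizer(d2, K)

    # neighbour lists for center proposals
    within = d2 <= config.center_hop_km**2
    nb_count = within.sum(axis=1)
    maxnb = int(nb_count.max())
    nb_idx = np.zeros((W, maxnb), dtype=np.int64)
    for c in range(W):
        idx = np.flatnonzero(within[c])
        nb_idx[c, : len(idx)] = idx
    log_nb = np.log(nb_count.astype(float))

    # initial centers: nearest water cell to the mean location, carried
    # forward/backward through undetected primaries
    xy_all = mask.cell_centers()
    s_init = np.zeros((n, P), dtype=np.int64)
    cell_of = {c: j for j, c in enumerate(wc)}
    for i in range(n):
        known = np.flatnonzero(seen[i])
        for t in range(P):
            tt = known[np.argmin(np.abs(known - t))]
            cell = mask.cell_index(loc[i, tt, 0], loc[i, tt, 1])
            if cell < 0 or not mask.water.ravel()[cell]:
                cell = mask.nearest_water_cell(loc[i, tt, 0], loc[i, tt, 1])
            s_init[i, t] = cell_of[int(cell)]

    n_entered = np.array([(first <= t).sum() for t in range(P)])
    pool = config.M - n_entered
    if np.any(pool < 0):
        raise ValueError("augmentation exhausted: increase M")

    n_keep = (config.n_iter - config.n_burn) // config.thin
    C = config.n_chains
    dens_out = np.zeros((C, n_keep, P, len(report)))
    abund_out = np.zeros((C, n_keep, P))
    p0_out = np.zeros((C, n_keep))
    sig_out = np.zeros((C, n_keep))
    beta_out = np.zeros((C, n_keep))
    phi_out = np.zeros((C, n_keep, max(P - 1, 1)))

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(C)

    arange_n = np.arange(n)
    for chain in range(C):
        rng = np.random.default_rng(chain_seeds[chain])
        st = _ChainState(
            s=s_init.copy(),
            a=np.full(n, P - 1, dtype=np.int64),
            w=seen.copy(),
            p0=config.fix_p0 if config.fix_p0 is not None else config.p0_init,
            sigma=config.fix_sigma if config.fix_sigma is not None else config.sigma_init,
            beta=0.0,
            psi=np.full(P, 0.4),
            phi=np.full(max(P - 1, 1), 0.7),
        )
        keep = 0
        for it in range(config.n_iter):
            _sweep(st, rng, config, n, P, K, W,
                   xy, isl, d_eff, detcount, seen, first, last, loc,
                   sm2, logZ, logS, nb_idx, nb_count, log_nb, arange_n, pool)
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                counts, total = _realized_counts(st, rng, config, n, P, K, W,
                                                 isl, d_eff, seen, pool,
                                                 report_masks)
                dens_out[chain, keep] = counts / report_areas[None, :]
                abund_out[chain, keep] = total
                p0_out[chain, keep] = st.p0
                sig_out[chain, keep] = st.sigma
                beta_out[chain, keep] = st.beta
                phi_out[chain, keep, : max(P - 1, 1)] = st.phi
                keep += 1

    # convergence diagnostics on scalar parameters
    rhats = {"p0": split_rhat(p0_out), "sigma": split_rhat(sig_out),
             "beta_island": split_rhat(beta_out)}
    for j in range(P - 1):
        rhats[f"phi_{j + 1}"] = split_rhat(phi_out[:, :, j])
    bad = {k: v for k, v in rhats.items()
           if np.isfinite(v) and v > config.rhat_warn
           and not (k == "p0" and config.fix_p0 is not None)
           and not (k == "sigma" and config.fix_sigma is not None)}
    if bad:
        warnings.warn(f"possible non-convergence, split-Rhat > {config.rhat_warn}: {bad}")

    flat = lambda arr: arr.reshape(-1, *arr.shape[2:])
    return PosteriorDraws(
        density=flat(dens_out),
        abundance_mask=flat(abund_out),
        p0=flat(p0_out),
        sigma=flat(sig_out),
        beta_island=flat(beta_out),
        phi=flat(phi_out)[:, : max(P - 1, 1)] if P > 1 else np.zeros((C * n_keep, 0)),
        strata=report,
        meta={
            "n_chains": C,
            "n_iter": config.n_iter,
            "n_burn": config.n_burn,
            "thin": config.thin,
            "seed": config.seed,
            "rhat": rhats,
            "areas_in_mask": dict(zip(report, report_areas)),
            "n_observed": n,
        },
    )


def _detection_probs(p0, sigma, d_eff):
    p = p0 * np.exp(-(d_eff**2) / (2.0 * sigma**2))
    return np.clip(p, 1e-300, 1.0 - 1e-12)


class _LocationNormalizer:
    """log water-truncation normalizers of the mean-location kernel.

    Recorded locations are redrawn until they fall on water, so the mean
    of k detection locations is modelled as a water-restricted Gaussian
    around the center with scale sigma/sqrt(k); ignoring the restriction
    biases centers away from shorelines.  Returns a (K, W) array of
    log-normalizers for k = 1..K, memoized on sigma.
    """

    def __init__(self, d2: np.ndarray, max_k: int):
        self._d2 = d2
        self._max_k = max_k
        self._sigma = None
        self._value = None

    def __call__(self, sigma: float) -> np.ndarray:
        if sigma != self._sigma:
            ks = np.arange(1, self._max_k + 1)[:, None, None]
            self._value = np.log(
                np.exp(-ks * self._d2[None, :, :] / (2.0 * sigma**2)).sum(axis=2)
            )
            self._sigma = sigma
        return self._value


def _sweep(st, rng, config, n, P, K, W, xy, isl, d_eff, detcount, seen,
           first, last, loc, sm2, logZ, logS, nb_idx, nb_count, log_nb,
           arange_n, pool):
    pdet = _detection_probs(st.p0, st.sigma, d_eff)
    logp = np.log(pdet)
    log1mp = np.log1p(-pdet)
    s2 = 2.0 * st.sigma**2
    lS = logS(st.sigma)

    # --- 1. activity centers -----------------------------------------
    for t in range(P):
        active = first <= t
        if not active.any():
            continue
        ai = np.flatnonzero(active)
        cur = st.s[ai, t]
        u = rng.random(len(ai))
        prop = nb_idx[cur, np.floor(u * nb_count[cur]).astype(np.int64)]
        dlog = np.zeros(len(ai))
        is_entry = first[ai] == t
        dlog += np.where(is_entry, st.beta * (isl[prop] - isl[cur]), 0.0)
        if t > 0:
            prev = st.s[ai, t - 1]
            d_new = ((xy[prop] - xy[prev]) ** 2).sum(axis=1)
            d_old = ((xy[cur] - xy[prev]) ** 2).sum(axis=1)
            dlog += np.where(~is_entry, -(d_new - d_old) / sm2, 0.0)
        if t < P - 1:
            nxt = st.s[ai, t + 1]
            d_new = ((xy[nxt] - xy[prop]) ** 2).sum(axis=1)
            d_old = ((xy[nxt] - xy[cur]) ** 2).sum(axis=1)
            dlog += -(d_new - d_old) / sm2 - (logZ[prop] - logZ[cur])
        # closed-portion detection factor for included animal-periods;
        # the survival factor deliberately does not feed back into the
        # centers (two-stage robust-design composition)
        incl = seen[ai, t] | st.w[ai, t]
        k_it = detcount[ai, t]
        det_term = k_it * (logp[prop] - logp[cur]) + (K - k_it) * (
            log1mp[prop] - log1mp[cur]
        )
        dlog += np.where(incl, det_term, 0.0)
        has_loc = seen[ai, t]
        if has_loc.any():
            m = loc[ai, t]
            r_new = ((m - xy[prop]) ** 2).sum(axis=1)
            r_old = ((m - xy[cur]) ** 2).sum(axis=1)
            krow = np.maximum(k_it.astype(np.int64), 1) - 1
            dloc = -k_it * (r_new - r_old) / s2 - (lS[krow, prop] - lS[krow, cur])
            dlog += np.where(has_loc, dloc, 0.0)
        dlog += log_nb[cur] - log_nb[prop]  # Hastings correction
        acc = np.log(rng.random(len(ai))) < dlog
        st.s[ai[acc], t] = prop[acc]

    # --- 2. death times ----------------------------------------------
    if P > 1:
        lphi = np.log(st.phi)
        l1mphi = np.log1p(-st.phi)
        cphi = np.concatenate([[0.0], np.cumsum(lphi)])  # (P,)
        nd = K * log1mp[st.s]  # (n, P): non-detection cost if alive
        cnd = np.cumsum(nd, axis=1)
        tt = np.arange(P)[None, :]
        logw = cphi[None, :P] + cnd - cnd[arange_n, last][:, None]
        logw += np.where(tt < P - 1, np.concatenate([l1mphi, [0.0]])[None, :P], 0.0)
        logw[tt < last[:, None]] = -np.inf
        g = rng.gumbel(size=logw.shape)
        st.a = np.argmax(logw + g, axis=1)

        # --- 3. survival ---------------------------------------------
        for j in range(P - 1):
            at_risk = (first <= j) & (st.a >= j)
            srv = int((at_risk & (st.a >= j + 1)).sum())
            die = int((at_risk & (st.a == j)).sum())
            st.phi[j] = rng.beta(1 + srv, 1 + die)

    # --- 4. per-primary inclusion (closed portion) -------------------
    # Detected animal-periods are certain inclusions.  Observed
    # individuals undetected in a primary (after first capture) get an
    # explicit inclusion flag with non-detection likelihood at their
    # center; slots not yet entered (never-observed, or observed but
    # first detected later) are collapsed, with centers marginalized
    # over the intensity surface.
    w_int = np.exp(st.beta * isl)
    pi = w_int / w_int.sum()
    q0_cell = np.exp(K * log1mp)
    q0 = float(pi @ q0_cell)
    M = int(config.M)
    tt_all = np.arange(P)[None, :]
    undet = (~seen) & (first[:, None] <= tt_all)  # entered but undetected
    q_it = q0_cell[st.s]  # (n, P) non-detection prob at current centers
    for t in range(P):
        psi = st.psi[t]
        # explicit inclusion for entered-undetected periods
        rows = np.flatnonzero(undet[:, t])
        if len(rows):
            q = q_it[rows, t]
            p_in = psi * q / (psi * q + (1.0 - psi))
            st.w[rows, t] = rng.random(len(rows)) < p_in
        # collapsed never-entered slots
        num = psi * q0
        p_incl = num / (num + (1.0 - psi))
        B = rng.binomial(pool[t], p_incl)
        n_incl = int(seen[:, t].sum()) + int(st.w[rows, t].sum()) + B
        st.psi[t] = rng.beta(1 + n_incl, 1 + M - n_incl)

    # --- 5. p0 / sigma -----------------------------------------------
    if config.fix_p0 is None or config.fix_sigma is None:
        aug_counts = _sample_aug_cells(st, rng, P, K, W, isl, log1mp, pool)
        ll_cur = _det_loglik(st, config, n, P, K, xy, d_eff, detcount, seen,
                             first, last, loc, aug_counts, logS, st.p0, st.sigma)
        if config.fix_p0 is None:
            logit = np.log(st.p0 / (1 - st.p0)) + rng.normal(0, config.prop_sd_logit_p0)
            p0_new = 1.0 / (1.0 + np.exp(-logit))
            ll_new = _det_loglik(st, config, n, P, K, xy, d_eff, detcount, seen,
                                 first, last, loc, aug_counts, logS, p0_new, st.sigma)
            # uniform prior on p0; logit-transform Jacobian
            dj = np.log(p0_new * (1 - p0_new)) - np.log(st.p0 * (1 - st.p0))
            if np.log(rng.random()) < ll_new - ll_cur + dj:
                st.p0, ll_cur = p0_new, ll_new
        if config.fix_sigma is None:
            sig_new = st.sigma * np.exp(rng.normal(0, config.prop_sd_log_sigma))
            ll_new = _det_loglik(st, config, n, P, K, xy, d_eff, detcount, seen,
                                 first, last, loc, aug_counts, logS, st.p0, sig_new)
            dpr = (
                -(sig_new**2 - st.sigma**2) / (2 * config.sigma_prior_scale**2)
                + np.log(sig_new) - np.log(st.sigma)  # log-transform Jacobian
            )
            if np.log(rng.random()) < ll_new - ll_cur + dpr:
                st.sigma, ll_cur = sig_new, ll_new

        # --- 6. island coefficient -----------------------------------
        entry_isl = float(isl[st.s[arange_n, first]].sum())
        aug_isl = float((aug_counts @ isl).sum())
        n_draws = n + float(aug_counts.sum())
        n_isl_draws = entry_isl + aug_isl
        n1 = isl.sum()
        n0 = len(isl) - n1

        def beta_ll(b):
            return n_isl_draws * b - n_draws * np.log(n0 + np.exp(b) * n1) - b**2 / (
                2 * config.beta_prior_sd**2
            )

        b_new = st.beta + rng.normal(0, config.prop_sd_beta)
        if np.log(rng.random()) < beta_ll(b_new) - beta_ll(st.beta):
            st.beta = b_new


def _sample_aug_cells(st, rng, P, K, W, isl, log1mp, pool):
    """Cells of included never-detected slots, (P, W) counts."""
    w_int = np.exp(st.beta * isl)
    pi = w_int / w_int.sum()
    weights = pi * np.exp(K * log1mp)
    q0 = weights.sum()
    pcell = weights / q0
    counts = np.zeros((P, W), dtype=np.int64)
    for t in range(P):
        num = st.psi[t] * q0
        p_incl = num / (num + (1.0 - st.psi[t]))
        B = int(rng.binomial(pool[t], p_incl))
        if pool[t] > 0 and B == pool[t]:
            raise ValueError(
                "augmentation exhausted (all slots included); rerun with larger M"
            )
        if B > 0:
            counts[t] = rng.multinomial(B, pcell)
    return counts


def _det_loglik(st, config, n, P, K, xy, d_eff, detcount, seen, first, last,
                loc, aug_counts, logS, p0, sigma):
    """Detection + location log-likelihood for (p0, sigma) updates.

    Combines the closed-portion factor (detected periods plus included
    undetected periods) with the survival-factor non-detections after
    the last capture.  The per-detection location term is a
    water-truncated Gaussian around the center; only the per-primary
    mean location is retained as data, so the within-primary spread's
    sigma information is forgone.
    """
    pdet = _detection_probs(p0, sigma, d_eff)
    logp = np.log(pdet)
    log1mp = np.log1p(-pdet)
    incl = seen | st.w
    cells = st.s
    ll = float(
        np.where(incl, detcount * logp[cells] + (K - detcount) * log1mp[cells], 0.0).sum()
    )
    if seen.any():
        r2 = ((loc - xy[cells]) ** 2).sum(axis=2)
        lS = logS(sigma)
        krow = np.maximum(detcount.astype(np.int64), 1) - 1
        ll += float(
            np.where(seen, -detcount * r2 / (2 * sigma**2) - lS[krow, cells], 0.0).sum()
        )
    ll += float((aug_counts.sum(axis=0) * K * log1mp).sum())
    return ll


def _realized_counts(st, rng, config, n, P, K, W, isl, d_eff, seen, pool,
                     report_masks):
    """Per-primary stratum counts of included activity centers."""
    pdet = _detection_probs(st.p0, st.sigma, d_eff)
    log1mp = np.log1p(-pdet)
    aug = _sample_aug_cells(st, rng, P, K, W, isl, log1mp, pool)
    counts = np.zeros((P, len(report_masks)))
    total = np.zeros(P)
    for t in range(P):
        incl = seen[:, t] | st.w[:, t]
        cells = st.s[incl, t]
        occ = np.bincount(cells, minlength=W) + aug[t]
        total[t] = occ.sum()
        for j, m in enumerate(report_masks):
            counts[t, j] = occ[m].sum()
    return counts, total
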