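"""Likelihood-ratio engines for single- and few-cell STR profiles.

Three routes to an LR are provided, mirroring forensic practice:

* :func:`single_source_profile_lr` — the hand calculation: per-locus
  subpopulation-corrected (Balding–Nichols) match probabilities for a full
  clean single-source profile, LR = 1/RMP;
* :class:`SemiContinuousModel` — a replicate-aware semi-continuous
  drop-out/drop-in model: peak presence only, per-contributor drop-out
  probability maximised over a grid, drop-in per allele at rate c·p_a,
  genotype priors from the Balding–Nichols sequential sampling formula
  conditioned on all typed references;
* :class:`QuantitativeModel` — a quantitative gamma peak-height model
  (maximum likelihood): observed heights gamma-distributed around
  mixture-weighted, degradation-decayed expectations with back/forward
  stutter redistribution, drop-out as the gamma mass below the analytical
  threshold, and exponential-height drop-in.

Both engines are fitted models in the statsmodels sense: construct with
data and hypotheses, call ``fit()``, receive an :class:`LRResult` with the
per-locus log10 LRs, the nuisance estimates and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammainc, gammaln


def _sigmoid(z: float) -> float:
    return 0.5 * (1.0 + math.tanh(0.5 * z))


def _logsumexp(arr: np.ndarray) -> float:
    m = float(np.max(arr))
    if not math.isfinite(m):
        return m
    return m + math.log(float(np.sum(np.exp(arr - m))))

from .panel import LocusPanel
from .profiles import (
    AlleleFrequencyTable,
    AnalyticalThresholds,
    Epg,
    ReferenceProfile,
    alleles_equal,
)

Q_ALLELE = "Q"  #: aggregate symbol for any allele not in the locus universe


def _key(allele: float) -> float:
    return round(float(allele), 1)


@dataclass
class Hypothesis:
    """A proposition: these known contributors plus n unknown individuals."""

    known_contributors: list[ReferenceProfile] = field(default_factory=list)
    n_unknowns: int = 0
    theta: float = 0.01

    def __post_init__(self) -> None:
        if self.noc < 1:
            raise ValueError("a hypothesis needs at least one contributor")
        if not 0 <= self.theta < 0.5:
            raise ValueError("theta must be in [0, 0.5)")

    @property
    def noc(self) -> int:
        return len(self.known_contributors) + self.n_unknowns


@dataclass
class LRResult:
    """Fitted likelihood-ratio result.

    ``log10_lr_total`` is the sum of ``per_locus_log10`` (−inf encodes
    LR = 0); ``nuisance_estimates`` carries fitted drop-out / mixture /
    degradation parameters per hypothesis; ``status`` is "ok" or "FAIL"
    (model validation failure — never silently rendered as a number).
    """

    log10_lr_total: float
    per_locus_log10: dict[str, float]
    hp: Hypothesis
    hd: Hypothesis
    model: str
    nuisance_estimates: dict = field(default_factory=dict)
    n_replicates: int = 1
    status: str = "ok"

    def to_dict(self) -> dict:
        """Machine-readable summary (JSON/YAML-safe)."""
        return {
            "model": self.model,
            "status": self.status,
            "n_replicates": self.n_replicates,
            "log10_lr_total": self.log10_lr_total,
            "per_locus_log10": dict(self.per_locus_log10),
            "nuisance_estimates": self.nuisance_estimates,
            "hp": {"known": [r.donor_id for r in self.hp.known_contributors],
                   "n_unknowns": self.hp.n_unknowns, "theta": self.hp.theta},
            "hd": {"known": [r.donor_id for r in self.hd.known_contributors],
                   "n_unknowns": self.hd.n_unknowns, "theta": self.hd.theta},
        }

    def summary(self) -> str:
        lines = [
            f"{'Likelihood ratio summary':^46}",
            "=" * 46,
            f"model:        {self.model}",
            f"replicates:   {self.n_replicates}",
            f"Hp: {len(self.hp.known_contributors)} known + {self.hp.n_unknowns} unknown"
            f"   Hd: {len(self.hd.known_contributors)} known + {self.hd.n_unknowns} unknown",
            f"theta:        {self.hp.theta}",
            f"status:       {self.status}",
            "-" * 46,
            f"{'locus':<12}{'log10 LR':>12}",
        ]
        for locus, v in self.per_locus_log10.items():
            lines.append(f"{locus:<12}{v:>12.4f}")
        lines.append("-" * 46)
        lines.append(f"{'total log10 LR':<14}{self.log10_lr_total:>10.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Balding–Nichols genotype probabilities


def locus_match_probability(
    genotype: tuple[float, float], freqs: AlleleFrequencyTable, locus: str
) -> float:
    """Theta-corrected single-source match probability at one locus.

    Heterozygous: 2[θ+(1−θ)p_i][θ+(1−θ)p_j] / ((1+θ)(1+2θ));
    homozygous:   [3θ+(1−θ)p_i][2θ+(1−θ)p_i] / ((1+θ)(1+2θ)).
    """
    theta = freqs.theta
    i, j = genotype
    p_i = freqs.frequency(locus, i)
    denom = (1 + theta) * (1 + 2 * theta)
    if alleles_equal(i, j):
        return ((3 * theta + (1 - theta) * p_i) * (2 * theta + (1 - theta) * p_i)) / denom
    p_j = freqs.frequency(locus, j)
    return (2 * (theta + (1 - theta) * p_i) * (theta + (1 - theta) * p_j)) / denom


def single_source_profile_lr(
    profile: ReferenceProfile,
    freqs: AlleleFrequencyTable,
    loci: Sequence[str] | None = None,
    partial: bool = False,
) -> LRResult:
    """The hand-calculated LR of a full clean single-source profile.

    Per locus, log10 LR = −log10(match probability); the total equals
    log10(1/RMP).
    """
    use_loci = list(loci) if loci is not None else freqs.loci
    per_locus = {}
    for locus in use_loci:
        try:
            g = profile.genotype(locus)
        except KeyError:
            if partial:
                continue
            raise
        per_locus[locus] = -math.log10(locus_match_probability(g, freqs, locus))
    hp = Hypothesis([profile], 0, theta=freqs.theta)
    hd = Hypothesis([], 1, theta=freqs.theta)
    return LRResult(
        log10_lr_total=sum(per_locus.values()),
        per_locus_log10=per_locus,
        hp=hp,
        hd=hd,
        model="single_source",
    )


class _LocusFreqs:
    """Frequency lookup over a locus universe with a Q residual allele."""

    def __init__(self, freqs: AlleleFrequencyTable, locus: str, universe: list):
        self.p = {}
        total = 0.0
        for a in universe:
            if a == Q_ALLELE:
                continue
            f = freqs.frequency(locus, a)
            self.p[a] = f
            total += f
        self.p[Q_ALLELE] = max(1.0 - total, freqs.min_frequency)

    def __call__(self, a) -> float:
        return self.p[a]


def _bn_genotype_logprob(
    genotype: tuple, counts: dict, m: int, freq, theta: float
) -> float:
    """Sequential Balding–Nichols probability of an unordered genotype."""

    def cond(a, counts, m):
        if theta == 0.0:
            return freq(a)
        return (counts.get(a, 0) * theta + (1 - theta) * freq(a)) / (1 + (m - 1) * theta)

    i, j = genotype
    p1 = cond(i, counts, m)
    counts2 = dict(counts)
    counts2[i] = counts2.get(i, 0) + 1
    p2 = cond(j, counts2, m + 1)
    prob = p1 * p2 if i == j else 2 * p1 * p2
    return math.log(prob) if prob > 0 else -math.inf


def _conditioning_counts(
    refs: Sequence[ReferenceProfile], locus: str, universe_keys: set
) -> tuple[dict, int]:
    counts: dict = {}
    m = 0
    for ref in refs:
        for a in ref.genotype(locus):
            k = _key(a)
            if k not in universe_keys:
                k = Q_ALLELE
            counts[k] = counts.get(k, 0) + 1
            m += 1
    return counts, m


# ---------------------------------------------------------------------------
# semi-continuous engine


class SemiContinuousModel:
    """Replicate-aware semi-continuous drop-out/drop-in LR model.

    Peak heights are ignored; the data are the presence/absence patterns of
    alleles across replicates.  Per hypothesis, the locus likelihood sums
    over genotype assignments to the contributors (Balding–Nichols priors
    conditioned on every typed reference of either hypothesis) the product
    over replicates of per-allele detection terms: each carried allele copy
    is independently detected with probability 1−d_k (homozygotes carry two
    independent chances, so homozygote drop-out is d_k²); unexplained
    observed alleles are drop-in with probability c·p_a each, at most
    ``max_dropins`` per locus per replicate; a replicate with no drop-in
    contributes a factor 1−c.  Drop-out d_k is shared across loci and
    maximised per contributor on a grid, separately under Hp and Hd.
    """

    def __init__(
        self,
        replicates: Sequence[Epg],
        hp: Hypothesis,
        hd: Hypothesis,
        freqs: AlleleFrequencyTable,
        loci: Sequence[str] | None = None,
        drop_in_rate: float = 0.0164,
        dropout_grid: np.ndarray | None = None,
        fixed_dropout: float | None = None,
        max_dropins: int = 2,
        max_noc: int = 3,
    ) -> None:
        if not replicates:
            raise ValueError("at least one replicate is required")
        for h in (hp, hd):
            if h.noc > max_noc:
                raise ValueError(
                    f"NOC {h.noc} exceeds the exact-enumeration guard ({max_noc})"
                )
        self.replicates = list(replicates)
        self.hp, self.hd = hp, hd
        self.freqs = freqs
        self.loci = list(loci) if loci is not None else freqs.loci
        self.c = drop_in_rate
        self.fixed_dropout = fixed_dropout
        self.max_dropins = max_dropins
        if dropout_grid is not None:
            self.grid = np.asarray(dropout_grid, dtype=float)
        else:
            self.grid = None  # resolved per hypothesis (NOC-dependent)

    # -- internals ----------------------------------------------------------

    def _grid_for(self, n_contrib: int) -> np.ndarray:
        if self.fixed_dropout is not None:
            return np.array([self.fixed_dropout], dtype=float)
        if self.grid is not None:
            return self.grid
        step = 0.01 if n_contrib <= 2 else 0.05
        return np.arange(step, 1.0, step)

    def _universe(self, locus: str) -> list:
        keys: list = []
        seen = set()

        def add(k):
            if k not in seen:
                seen.add(k)
                keys.append(k)

        for rep in self.replicates:
            for a in rep.alleles(locus):
                add(_key(a))
        for h in (self.hp, self.hd):
            for ref in h.known_contributors:
                for a in ref.genotype(locus):
                    add(_key(a))
        add(Q_ALLELE)
        return keys

    def _locus_likelihood(
        self, locus: str, hypothesis: Hypothesis, cond_refs, dropout_mesh
    ) -> np.ndarray:
        universe = self._universe(locus)
        universe_keys = set(universe)
        lf = _LocusFreqs(self.freqs, locus, universe)
        counts0, m0 = _conditioning_counts(cond_refs, locus, universe_keys)
        theta = hypothesis.theta

        knowns = [
            tuple(sorted(_key(a) for a in ref.genotype(locus)))
            for ref in hypothesis.known_contributors
        ]
        n_unknown = hypothesis.n_unknowns
        genos = [
            tuple(sorted((universe[i], universe[j]), key=lambda x: (x == Q_ALLELE, x)))
            for i in range(len(universe))
            for j in range(i, len(universe))
        ]

        observed = [frozenset(_key(a) for a in rep.alleles(locus)) for rep in self.replicates]

        n_contrib = len(knowns) + n_unknown
        grid_size = dropout_mesh[0].size if n_contrib else 1
        drop_cache: dict[tuple, np.ndarray] = {}

        def drop_term(pattern: tuple) -> np.ndarray:
            arr = drop_cache.get(pattern)
            if arr is None:
                arr = np.ones(grid_size)
                for k, n in enumerate(pattern):
                    if n:
                        arr = arr * dropout_mesh[k] ** n
                drop_cache[pattern] = arr
            return arr

        total = np.zeros(grid_size)
        for unknown_genos in itertools.product(genos, repeat=n_unknown):
            logprior = 0.0
            counts, m = dict(counts0), m0
            for g in unknown_genos:
                logprior += _bn_genotype_logprob(g, counts, m, lf, theta)
                if logprior == -math.inf:
                    break
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
                m += 2
            if logprior == -math.inf:
                continue
            all_genos = knowns + list(unknown_genos)
            carried: dict = {}
            for k, g in enumerate(all_genos):
                for a in g:
                    pattern = carried.setdefault(a, [0] * n_contrib)
                    pattern[k] += 1
            factor = np.ones(grid_size)
            for obs in observed:
                rep_factor = np.ones(grid_size)
                for a, pattern in carried.items():
                    drop = drop_term(tuple(pattern))
                    rep_factor = rep_factor * ((1.0 - drop) if a in obs else drop)
                dropins = [a for a in obs if a not in carried]
                if len(dropins) > self.max_dropins:
                    rep_factor = np.zeros(grid_size)
                elif dropins:
                    for a in dropins:
                        rep_factor = rep_factor * (self.c * lf(a))
                else:
                    rep_factor = rep_factor * (1.0 - self.c)
                factor = factor * rep_factor
            total = total + math.exp(logprior) * factor
        return total

    def _hypothesis_loglik(self, hypothesis: Hypothesis, cond_refs):
        n_contrib = len(hypothesis.known_contributors) + hypothesis.n_unknowns
        grid = self._grid_for(n_contrib)
        if n_contrib:
            mesh = [m.ravel() for m in np.meshgrid(*([grid] * n_contrib), indexing="ij")]
        else:
            mesh = [np.array([0.0])]
        per_locus = {}
        with np.errstate(divide="ignore"):
            for locus in self.loci:
                lik = self._locus_likelihood(locus, hypothesis, cond_refs, mesh)
                per_locus[locus] = np.log10(lik)
        total = np.sum([per_locus[locus] for locus in self.loci], axis=0)
        best = int(np.argmax(total))
        d_hat = [float(mesh[k][best]) for k in range(n_contrib)]
        return (
            float(total[best]),
            {locus: float(arr[best]) for locus, arr in per_locus.items()},
            d_hat,
        )

    # -- public -------------------------------------------------------------

    def fit(self) -> LRResult:
        cond_refs = _dedupe_refs(self.hp.known_contributors + self.hd.known_contributors)
        lp, lp_locus, d_p = self._hypothesis_loglik(self.hp, cond_refs)
        ld, ld_locus, d_d = self._hypothesis_loglik(self.hd, cond_refs)
        per_locus = {
            locus: lp_locus[locus] - ld_locus[locus] for locus in self.loci
        }
        total = lp - ld
        if math.isnan(total):  # 0/0 at some locus: treat as exclusion
            total = -math.inf
        return LRResult(
            log10_lr_total=total,
            per_locus_log10=per_locus,
            hp=self.hp,
            hd=self.hd,
            model="semi_continuous",
            nuisance_estimates={
                "dropout_hp": d_p,
                "dropout_hd": d_d,
                "drop_in_rate": self.c,
            },
            n_replicates=len(self.replicates),
        )


def _dedupe_refs(refs: Sequence[ReferenceProfile]) -> list[ReferenceProfile]:
    out, seen = [], set()
    for r in refs:
        if r.donor_id not in seen:
            seen.add(r.donor_id)
            out.append(r)
    return out


def semicontinuous_replicate_lr(
    replicates: Sequence[Epg],
    hp: Hypothesis,
    hd: Hypothesis,
    freqs: AlleleFrequencyTable,
    **kwargs,
) -> LRResult:
    """Functional wrapper over :class:`SemiContinuousModel`."""
    return SemiContinuousModel(replicates, hp, hd, freqs, **kwargs).fit()


# ---------------------------------------------------------------------------
# quantitative gamma engine


@dataclass
class QuantParams:
    """Parameters of the quantitative gamma peak-height model."""

    mu: float = 1000.0
    omega: float = 0.3
    mix_props: tuple[float, ...] = (1.0,)
    delta_k: tuple[float, ...] = (0.99,)
    xi_b: float = 0.02
    xi_f: float = 0.01
    dropin_rate: float = 0.0164
    dropin_lambda: float = 0.01

    def __post_init__(self) -> None:
        if abs(sum(self.mix_props) - 1.0) > 1e-9:
            raise ValueError("mix_props must sum to 1")
        if self.xi_b + self.xi_f >= 1:
            raise ValueError("xi_b + xi_f must be < 1")


class QuantitativeModel:
    """Quantitative gamma peak-height replicate LR model (MLE).

    Observed heights at each allele position are gamma-distributed with
    mean mu·mix_k·dose·delta_k^((size−size_ref)/100), redistributed by
    back/forward stutter proportions; expected-but-absent positions
    contribute the gamma mass below the dye analytical threshold
    (drop-out); unexpected peaks contribute drop-in (rate × exponential
    height law above the threshold).  The likelihood is maximised over
    (mu, omega, mixture proportions, per-contributor degradation, stutter
    proportions) with ``n_starts`` random restarts under each hypothesis;
    LR is the ratio of the maximised likelihoods.  Restricted to NOC ≤ 2,
    as the reference quantitative tools are only recommended for small
    mixtures.
    """

    OMEGA_MIN = 0.05

    def __init__(
        self,
        replicates: Sequence[Epg],
        hp: Hypothesis,
        hd: Hypothesis,
        freqs: AlleleFrequencyTable,
        panel: LocusPanel,
        at: AnalyticalThresholds | None = None,
        qinit: QuantParams | None = None,
        n_starts: int = 3,
        seed: int = 0,
        degradation_max: float = 0.1,
        size_ref: float = 125.0,
        dropin_law: str = "uniform",
        dropin_cap: float = 30000.0,
        loci: Sequence[str] | None = None,
        fit_stutter: bool = True,
        stutter_cv_factor: float = 3.0,
        omega_max: float = 2.5,
        hb_bounds=None,
        hb_k: float = 2.0,
        hb_share_threshold: float = 0.999,
    ) -> None:
        for h in (hp, hd):
            if h.noc > 2:
                raise ValueError(
                    "quantitative engine supports NOC <= 2; the reference "
                    "quantitative tools are only recommended on mixtures of "
                    "up to four people and this implementation is narrower"
                )
        if not replicates:
            raise ValueError("at least one replicate is required")
        self.replicates = list(replicates)
        self.hp, self.hd = hp, hd
        self.freqs = freqs
        self.panel = panel
        self.at = at or AnalyticalThresholds()
        self.qinit = qinit or QuantParams()
        self.n_starts = n_starts
        self.seed = seed
        self.deg_max = degradation_max
        self.size_ref = size_ref
        self.dropin_law = dropin_law
        self.dropin_cap = dropin_cap
        self.loci = list(loci) if loci is not None else freqs.loci
        self.fit_stutter = fit_stutter
        self.stutter_cv_factor = stutter_cv_factor
        self.omega_max = omega_max
        self.hb_bounds = hb_bounds
        self.hb_k = hb_k
        self.hb_share_threshold = hb_share_threshold

    # -- model structure ----------------------------------------------------

    def _locus_structures(self, hypothesis: Hypothesis):
        """Per locus: positions, observed heights, genotype dose tensors."""
        cond_refs = _dedupe_refs(self.hp.known_contributors + self.hd.known_contributors)
        structures = []
        for locus in self.loci:
            locus_rec = self.panel.locus(locus)
            at = self.at.threshold(locus_rec.dye)
            universe: list = []
            seen = set()

            def add(k):
                if k not in seen:
                    seen.add(k)
                    universe.append(k)

            for rep in self.replicates:
                for a in rep.alleles(locus):
                    add(_key(a))
            for h in (self.hp, self.hd):
                for ref in h.known_contributors:
                    for a in ref.genotype(locus):
                        add(_key(a))
            add(Q_ALLELE)
            lf = _LocusFreqs(self.freqs, locus, universe)
            counts0, m0 = _conditioning_counts(cond_refs, locus, set(universe))

            # positions: universe plus +/-1 repeat stutter targets of real alleles
            positions: list = list(universe)
            for a in universe:
                if a == Q_ALLELE:
                    continue
                for shift in (-1.0, +1.0):
                    k = _key(a + shift)
                    if k not in positions:
                        positions.append(k)
            pos_index = {a: i for i, a in enumerate(positions)}
            sizes = np.array(
                [
                    locus_rec.size_of(a) if a != Q_ALLELE else locus_rec.size_of(12.0)
                    for a in positions
                ]
            )

            knowns = [
                tuple(sorted(_key(x) for x in ref.genotype(locus)))
                for ref in hypothesis.known_contributors
            ]
            genos = [
                tuple(sorted((universe[i], universe[j]), key=lambda x: (x == Q_ALLELE, str(x))))
                for i in range(len(universe))
                for j in range(i, len(universe))
            ]
            assignments, logpriors = [], []
            for unknown_genos in itertools.product(genos, repeat=hypothesis.n_unknowns):
                logprior = 0.0
                counts, m = dict(counts0), m0
                for g in unknown_genos:
                    logprior += _bn_genotype_logprob(g, counts, m, lf, hypothesis.theta)
                    if logprior == -math.inf:
                        break
                    for a in g:
                        counts[a] = counts.get(a, 0) + 1
                    m += 2
                if logprior == -math.inf:
                    continue
                assignments.append(list(knowns) + list(unknown_genos))
                logpriors.append(logprior)

            n_contrib = hypothesis.noc
            dose = np.zeros((len(assignments), len(positions), n_contrib))
            for ai, gsets in enumerate(assignments):
                for k, g in enumerate(gsets):
                    for a in g:
                        dose[ai, pos_index[a], k] += 1.0

            # positions reachable by each assignment: direct dose, dilated by
            # +/-1-repeat stutter when stutter proportions are strictly positive
            direct = dose.sum(axis=2) > 0  # (A, P)
            if self.fit_stutter or self.qinit.xi_b > 0 or self.qinit.xi_f > 0:
                expected = direct.copy()
                for a, i in pos_index.items():
                    if a == Q_ALLELE:
                        continue
                    for shift in (-1.0, +1.0):
                        j = pos_index.get(_key(a + shift))
                        if j is not None:
                            expected[:, i] |= direct[:, j]
            else:
                expected = direct

            c = self.qinit.dropin_rate
            lam = self.qinit.dropin_lambda
            reps = []
            for rep in self.replicates:
                h = np.zeros(len(positions))
                obs = np.zeros(len(positions), dtype=bool)
                for p in rep.peaks(locus):
                    k = _key(p.allele)
                    h[pos_index[k]] = p.height
                    obs[pos_index[k]] = True
                # drop-in term per assignment: fixed given c and lambda
                dropin = (~expected) & obs[None, :]
                n_di = dropin.sum(axis=1)
                di_term = np.zeros(expected.shape[0])
                for ai in range(expected.shape[0]):
                    if n_di[ai] == 0:
                        di_term[ai] = math.log1p(-c) if c < 1 else -math.inf
                    elif n_di[ai] > 2 or c <= 0:
                        di_term[ai] = -math.inf
                    else:
                        val = 0.0
                        for pi in np.nonzero(dropin[ai])[0]:
                            a = positions[pi]
                            p_a = lf.p.get(a, self.freqs.min_frequency)
                            if self.dropin_law == "uniform":
                                dens = 1.0 / max(self.dropin_cap - at, 1.0)
                            else:
                                dens = lam * math.exp(-lam * max(h[pi] - at, 0.0))
                            val += math.log(max(c * p_a * dens, 1e-300))
                        di_term[ai] = val
                reps.append((h, obs, di_term))

            # calibrated heterozygote-balance validity rule: a contributor's
            # het pair with one sister observed far beyond the calibrated
            # imbalance bounds and the other absent cannot be explained by
            # drop-out if that contributor is effectively the peak's sole
            # source; candidates are data-determined, the share test is
            # applied at the fitted optimum
            hb_candidates: list[tuple[int, int, int]] = []
            if self.hb_bounds is not None:
                for ai, gsets in enumerate(assignments):
                    for k, g in enumerate(gsets):
                        a1, a2 = g
                        if a1 == a2:
                            continue
                        i1, i2 = pos_index[a1], pos_index[a2]
                        for h_arr, obs_arr, _ in reps:
                            for io, ia in ((i1, i2), (i2, i1)):
                                if obs_arr[io] and not obs_arr[ia]:
                                    hh = float(h_arr[io])
                                    if hh > at and math.log10(hh / at) > (
                                        self.hb_k * self.hb_bounds.bounds(hh / 2.0)
                                    ):
                                        hb_candidates.append((ai, k, io))

            # stutter redistribution matrix target<-source for integer shifts
            back_map = np.full(len(positions), -1, dtype=int)
            fwd_map = np.full(len(positions), -1, dtype=int)
            for a, i in pos_index.items():
                if a == Q_ALLELE:
                    continue
                b = pos_index.get(_key(a - 1.0))
                f = pos_index.get(_key(a + 1.0))
                if b is not None:
                    back_map[i] = b
                if f is not None:
                    fwd_map[i] = f
            structures.append(
                dict(
                    locus=locus,
                    at=at,
                    positions=positions,
                    sizes=sizes,
                    dose=dose,
                    logpriors=np.array(logpriors),
                    reps=reps,
                    lf=lf,
                    back_map=back_map,
                    fwd_map=fwd_map,
                    expected=expected,
                    direct=direct,
                    hb_candidates=hb_candidates,
                )
            )
        return structures

    # -- likelihood ---------------------------------------------------------

    def _loglik(self, x: np.ndarray, structures, n_contrib: int,
                floor: bool = False) -> float:
        mu = math.exp(x[0])
        omega = self.OMEGA_MIN + (self.omega_max - self.OMEGA_MIN) * _sigmoid(x[1])
        idx = 2
        if n_contrib == 2:
            w = _sigmoid(x[idx])
            mix = np.array([w, 1.0 - w])
            idx += 1
        else:
            mix = np.array([1.0])
        deltas = []
        for _ in range(n_contrib):
            s = _sigmoid(x[idx])
            deltas.append(1.0 - self.deg_max * s)
            idx += 1
        deltas = np.array(deltas)
        if self.fit_stutter:
            xi_b = 0.3 * _sigmoid(x[idx])
            xi_f = 0.3 * _sigmoid(x[idx + 1])
        else:
            xi_b, xi_f = self.qinit.xi_b, self.qinit.xi_f
        shape = 1.0 / omega**2
        lgamma_shape = float(gammaln(shape))

        with np.errstate(divide="ignore", invalid="ignore"):
            return self._loglik_loop(structures, mu, omega, mix, deltas,
                                     xi_b, xi_f, shape, lgamma_shape, floor)

    def _loglik_loop(self, structures, mu, omega, mix, deltas, xi_b, xi_f,
                     shape, lgamma_shape, floor) -> float:
        total = 0.0
        for s in structures:
            dose = s["dose"]  # (A, P, K)
            sizes = s["sizes"]
            decay = deltas[None, :] ** ((sizes[:, None] - self.size_ref) / 100.0)  # (P, K)
            contrib = mu * mix[None, :] * decay  # (P, K)
            mean = np.einsum("apk,pk->ap", dose, contrib)  # (A, P)
            # stutter redistribution
            mean_s = (1.0 - xi_b - xi_f) * mean
            bm, fm = s["back_map"], s["fwd_map"]
            has_b = bm >= 0
            has_f = fm >= 0
            add = np.zeros_like(mean)
            add[:, bm[has_b]] += xi_b * mean[:, has_b]
            add[:, fm[has_f]] += xi_f * mean[:, has_f]
            mean_s = mean_s + add

            at = s["at"]
            expected = s["expected"]
            direct = s["direct"]
            # stutter-only positions carry a wider CV than allelic positions:
            # stutter ratios are far noisier than allele heights, and tying
            # them to the allelic omega would wash out genotype resolution
            f2 = self.stutter_cv_factor**2
            shape_arr = np.where(direct, shape, shape / f2)
            lgamma_arr = np.where(direct, lgamma_shape,
                                  float(gammaln(shape / f2)))
            var_mult = np.where(direct, 1.0, f2)
            scale = np.where(expected, mean_s, 1.0) * omega**2 * var_mult
            log_scale = np.log(scale)
            loc_log = s["logpriors"].copy()  # (A,)
            for h, obs, di_term in s["reps"]:
                term = np.zeros_like(mean_s)
                sel = expected & obs[None, :]
                if sel.any():
                    hh = np.broadcast_to(h[None, :], mean_s.shape)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        lp = (
                            (shape_arr - 1.0) * np.log(np.where(sel, hh, 1.0))
                            - hh / scale
                            - shape_arr * log_scale
                            - lgamma_arr
                        )
                    term[sel] = lp[sel]
                sel = expected & ~obs[None, :]
                if sel.any():
                    cdf = gammainc(shape_arr, at / scale)
                    lcdf = np.log(np.clip(cdf, 1e-300, 1.0))
                    term[sel] = lcdf[sel]
                loc_log = loc_log + term.sum(axis=1) + di_term
            if floor and s["hb_candidates"]:
                invalid = np.zeros(mean.shape[0], dtype=bool)
                for ai, k, pos in s["hb_candidates"]:
                    m_tot = mean[ai, pos]
                    if m_tot <= 0:
                        continue
                    if dose[ai, pos, k] * contrib[pos, k] >= (
                        self.hb_share_threshold * m_tot
                    ):
                        invalid[ai] = True
                loc_log = np.where(invalid, -np.inf, loc_log)
            total += _logsumexp(loc_log)
        return total

    def _n_params(self, n_contrib: int) -> int:
        return 2 + (1 if n_contrib == 2 else 0) + n_contrib + (2 if self.fit_stutter else 0)

    def _fit_hypothesis(self, hypothesis: Hypothesis, rng: np.random.Generator):
        from scipy.optimize import minimize

        structures = self._locus_structures(hypothesis)
        n_contrib = hypothesis.noc
        heights = [
            p.height for rep in self.replicates for locus in self.loci for p in rep.peaks(locus)
        ]
        mu0 = max(float(np.median(heights)) if heights else self.qinit.mu, 50.0)
        x0 = np.zeros(self._n_params(n_contrib))
        x0[0] = math.log(mu0)
        w0 = min(max((self.qinit.omega - self.OMEGA_MIN) / (self.omega_max - self.OMEGA_MIN), 0.05), 0.95)
        x0[1] = math.log(w0 / (1.0 - w0))
        # multi-start design: first start from x0; for two-contributor fits
        # the next two seed the mixture weight at the extremes so strongly
        # unbalanced optima are reachable; any further starts are random
        starts = [x0.copy()]
        if n_contrib == 2 and hypothesis.n_unknowns > 0:
            # strongly unbalanced optima matter when an unknown can absorb
            # or shed template; seed the mixture weight across its range
            for z in (-7.0, -4.0, 4.0, 7.0):
                xe = x0.copy()
                xe[2] = z
                starts.append(xe)
        while len(starts) < self.n_starts:
            starts.append(x0 + rng.normal(0.0, 0.4, size=x0.shape))
        best_x, best_floored = None, -math.inf
        objective = lambda x: -self._loglik(x, structures, n_contrib)
        for start, xs in enumerate(starts):
            if start:
                xs = xs + rng.normal(0.0, 0.05, size=x0.shape)
            try:
                res = minimize(
                    objective, xs, method="Nelder-Mead",
                    options={"maxiter": 90 * len(x0), "xatol": 1e-3, "fatol": 1e-4},
                )
                # restart polish: a fresh simplex at the optimum escapes
                # premature simplex collapse
                res = minimize(
                    objective, res.x, method="Nelder-Mead",
                    options={"maxiter": 45 * len(x0), "xatol": 1e-4, "fatol": 1e-6},
                )
            except (ValueError, FloatingPointError):
                continue
            if not np.isfinite(res.fun):
                continue
            # rank starts by the floored likelihood so an optimum relying on
            # an impossible drop-out never outranks a valid one
            floored = self._loglik(res.x, structures, n_contrib, floor=True)
            if floored > best_floored:
                best_x, best_floored = res.x, floored
        if best_x is None or not np.isfinite(best_floored):
            return None, None, structures
        return float(best_floored), best_x, structures

    def _per_locus(self, x: np.ndarray, structures, n_contrib: int) -> dict[str, float]:
        out = {}
        for s in structures:
            out[s["locus"]] = self._loglik(x, [s], n_contrib, floor=True)
        return out

    def _decode(self, x: np.ndarray, n_contrib: int) -> dict:
        mu = math.exp(x[0])
        omega = self.OMEGA_MIN + (self.omega_max - self.OMEGA_MIN) * _sigmoid(x[1])
        idx = 2
        if n_contrib == 2:
            w = _sigmoid(x[idx])
            mix = (w, 1.0 - w)
            idx += 1
        else:
            mix = (1.0,)
        deltas = []
        for _ in range(n_contrib):
            deltas.append(1.0 - self.deg_max * _sigmoid(x[idx]))
            idx += 1
        out = {"mu": mu, "omega": omega, "mix_props": mix, "delta_k": tuple(deltas)}
        if self.fit_stutter:
            out["xi_b"] = 0.3 * _sigmoid(x[idx])
            out["xi_f"] = 0.3 * _sigmoid(x[idx + 1])
        return out

    def fit_single(self, hypothesis: Hypothesis) -> dict | None:
        """MLE of the gamma model under one hypothesis.

        Returns the decoded parameter estimates plus the maximised
        log-likelihood, or None on model failure.  Useful for conditioned
        analyses such as mixture-proportion estimation with all
        contributors known.
        """
        rng = np.random.default_rng(self.seed)
        loglik, x, _ = self._fit_hypothesis(hypothesis, rng)
        if loglik is None:
            return None
        out = self._decode(x, hypothesis.noc)
        out["loglik"] = loglik
        return out

    def fit(self) -> LRResult:
        rng_p = np.random.default_rng(self.seed)
        rng_d = np.random.default_rng(self.seed)  # identical starts for both sides
        lp, xp, st_p = self._fit_hypothesis(self.hp, rng_p)
        ld, xd, st_d = self._fit_hypothesis(self.hd, rng_d)
        fail = LRResult(
            log10_lr_total=math.nan,
            per_locus_log10={},
            hp=self.hp,
            hd=self.hd,
            model="quantitative",
            status="FAIL",
            n_replicates=len(self.replicates),
        )
        if ld is None:
            return fail
        if lp is None:  # prosecution hypothesis cannot explain the data: LR = 0
            return LRResult(
                log10_lr_total=-math.inf,
                per_locus_log10={},
                hp=self.hp,
                hd=self.hd,
                model="quantitative",
                status="ok",
                n_replicates=len(self.replicates),
            )
        ln10 = math.log(10.0)
        locus_p = self._per_locus(xp, st_p, self.hp.noc)
        locus_d = self._per_locus(xd, st_d, self.hd.noc)
        if any(not math.isfinite(v) for v in locus_d.values()):
            return fail  # defense hypothesis invalid at its own optimum
        per_locus = {loc: (locus_p[loc] - locus_d[loc]) / ln10 for loc in locus_p}
        return LRResult(
            log10_lr_total=sum(per_locus.values()),
            per_locus_log10=per_locus,
            hp=self.hp,
            hd=self.hd,
            model="quantitative",
            nuisance_estimates={
                "hp": self._decode(xp, self.hp.noc),
                "hd": self._decode(xd, self.hd.noc),
            },
            n_replicates=len(self.replicates),
        )


def quantitative_replicate_lr(
    replicates: Sequence[Epg],
    hp: Hypothesis,
    hd: Hypothesis,
    freqs: AlleleFrequencyTable,
    panel: LocusPanel,
    qinit: QuantParams | None = None,
    n_starts: int = 3,
    **kwargs,
) -> LRResult:
    """Functional wrapper over :class:`QuantitativeModel`."""
    return QuantitativeModel(
        replicates, hp, hd, freqs, panel, qinit=qinit, n_starts=n_starts, **kwargs
    ).fit()


# ---------------------------------------------------------------------------
# database search


def database_search(
    replicates: Sequence[Epg],
    database: Sequence[ReferenceProfile],
    freqs: AlleleFrequencyTable,
    model: str = "semi_continuous",
    hd_unknowns: int = 1,
    hp_unknowns: int = 0,
    theta: float | None = None,
    panel: LocusPanel | None = None,
    **engine_kwargs,
) -> list[LRResult]:
    """LR of every database profile as the known contributor under Hp.

    Results are ordered by donor_id; per-profile engine failures are
    recorded with status "FAIL" and the search continues.
    """
    if not database:
        raise ValueError("database must be non-empty")
    theta = freqs.theta if theta is None else theta
    results = []
    for ref in sorted(database, key=lambda r: r.donor_id):
        hp = Hypothesis([ref], hp_unknowns, theta=theta)
        hd = Hypothesis([], hd_unknowns, theta=theta)
        try:
            if model == "semi_continuous":
                res = SemiContinuousModel(
                    replicates, hp, hd, freqs, **engine_kwargs
                ).fit()
            elif model == "quantitative":
                res = QuantitativeModel(
                    replicates, hp, hd, freqs, panel, **engine_kwargs
                ).fit()
            else:
                raise ValueError(f"unknown engine {model!r}")
        except ValueError:
            raise
        except Exception:  # engine numerical failure: record and continue
            res = LRResult(
                log10_lr_total=math.nan,
                per_locus_log10={},
                hp=hp,
                hd=hd,
                model=model,
                status="FAIL",
                n_replicates=len(replicates),
            )
        results.append(res)
    return results
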