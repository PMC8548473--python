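"""Synthetic dyadic corpus generator with known adaptation couplings.

Real dense recordings of child-parent interaction are not
distributable, so the analysis pipeline is exercised on simulated
corpora that reproduce the statistical shape such data are reported to
have: a parent (CDS) stratum drawing roughly 650 verb tokens per
session from a near-stationary Zipfian root lexicon with a Qal-dominant
binyan mixture (~80% of tokens), and a child (CS) stratum drawing
roughly 100 tokens per session from a growing inventory acquired in
frequency-rank order, producing punctuated construct activation.

Adaptation enters through two channels.  Current-session attunement
is token re-use: with probability ``1 - exp(-b)`` a child token
re-uses a wordform the parent produced in the same session (restricted
to the child's inventory), and a responsive share of parent tokens
re-uses the child's current wordforms, so each party's realized
wordform concentration transfers link-for-link.  Lagged couplings and
within-speaker persistence are log-linear opinion pools on the coupled
stratum's previous-session empirical shares.  Session-to-session
variation in what the dyad talks about is modeled as AR(1) lognormal
topic noise over the head vocabulary, and root sampling is stratified
by primary-binyan class so the calibrated binyan mixture survives any
amount of reweighting.  Ground-truth coupling coefficients are
serialized next to every simulated corpus so the lagged adaptation
models can be validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import inventory as inv
from .corpus import CorpusTable, from_records
from .measures import measure_table
from .models import assemble_network_frame, fit_density_lm
from .networks import build_network_series

_CONSONANTS = "bgdhwzHtyklmnspqr?cfx"  # romanized consonant pool for root labels


class SimulationError(ValueError):
    """Raised for infeasible simulation parameters."""


@dataclass
class SimParams:
    """Generator parameters; defaults encode the emulated study conditions.

    Token volumes and session counts follow the reported corpus shape
    (47 sessions between 664 and 810 days of age; ~31k CDS vs ~4.6k CS
    verb tokens overall).  Current-session couplings act as token
    re-use: with probability ``1 - exp(-b)`` a token re-uses a wordform
    the partner just produced, so the partner's realized concentration
    transfers link-for-link.  Lagged and self couplings are log-linear
    pool weights on the smoothed empirical share of the coupled
    stratum's previous session.  Coefficients are the simulator's
    ground truth, not estimates.
    """

    dyad_id: str = "dyad1"
    n_sessions: int = 47
    age_start_days: int = 664
    age_end_days: int = 810
    cds_tokens_mean: float = 650.0
    cs_tokens_mean: float = 100.0
    token_dispersion: float = 10.0  # negative-binomial shape; var = mu + mu^2/k
    cds_n_roots: int = 400
    root_zipf_exponent: float = 1.05
    root_zipf_offset: float = 15.0  # Zipf-Mandelbrot offset; flattens the head
    binyan_shares: dict = field(
        default_factory=lambda: {
            "Qal": 0.80,
            "Piel": 0.07,
            "Hifil": 0.06,
            "Hitpael": 0.03,
            "Nifal": 0.02,
            "Hufal": 0.01,
            "Pual": 0.01,
        }
    )
    binyan_mix_noise: float = 0.05  # per-token chance to re-draw binyan from mixture
    pattern_zipf_exponent: float = 1.0
    cs_initial_roots: int = 25
    cs_root_growth: float = 3.0  # known roots added per session (rank order)
    cs_initial_patterns: int = 12
    cs_pattern_growth: float = 1.5
    parent_persistence: float = 2.0  # parent re-use of own N-1 usage (priming)
    parent_routine: float = 0.0  # pool weight damping the parent's dormant constructs
    coupling_self: float = 0.1  # child persistence on own N-1 usage
    coupling_parent_current: float = 0.3  # child <- CDS current session
    coupling_parent_prior: float = 0.1  # child <- CDS at N-1
    coupling_child_current: float = 0.3  # parent <- CS current session
    coupling_child_prior: float = 0.1  # parent <- CS at N-1
    expansion_gain: float = 2.0  # parent breadth response to low child density
    responsive_fraction: float = 0.3  # share of CDS tokens drawn after the child
    session_topic_sd: float = 1.3  # sd of per-session lognormal topic noise (CDS roots)
    topic_persistence: float = 0.9  # AR(1) of topic noise across sessions
    topic_head_roots: int = 150  # topic noise touches only this many head roots
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise SimulationError("n_sessions must be >= 1")
        if self.age_end_days <= self.age_start_days:
            raise SimulationError("age_end_days must exceed age_start_days")
        if min(self.cds_tokens_mean, self.cs_tokens_mean) < 1:
            raise SimulationError("tokens-per-session means must be >= 1")
        shares = np.array(list(self.binyan_shares.values()), dtype=float)
        if (shares < 0).any() or (shares > 1).any() or abs(shares.sum() - 1) > 1e-9:
            raise SimulationError("binyan_shares must be probabilities summing to 1")
        if not 0 <= self.responsive_fraction <= 1:
            raise SimulationError("responsive_fraction must be in [0, 1]")
        max_roots = self.cs_initial_roots + self.cs_root_growth * (self.n_sessions - 1)
        if max_roots > self.cds_n_roots:
            raise SimulationError(
                f"child root inventory ({max_roots:.0f}) would exceed the parent "
                f"inventory ({self.cds_n_roots})"
            )
        n_patterns = len(inv.full_inflection_inventory())
        max_pat = self.cs_initial_patterns + self.cs_pattern_growth * (self.n_sessions - 1)
        if max_pat > n_patterns:
            raise SimulationError(
                f"child pattern inventory ({max_pat:.0f}) would exceed the "
                f"{n_patterns}-category inventory"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_params(**overrides) -> SimParams:
    """Calibration defaults: 47 sessions, ages 664-810 days, Qal share 0.80."""
    return SimParams(**overrides)


def recovery_params(**overrides) -> SimParams:
    """The parameter-recovery condition: strong attunement, mature child.

    Couplings are set strong and positive and the child's inventory is
    stationary and established, isolating the adaptation channels from
    the growth trend so the lagged density models face a clean
    estimation problem at calibration scale (47 sessions, reported
    token volumes).
    """
    cond = dict(
        coupling_parent_current=2.0,
        coupling_child_current=2.0,
        coupling_parent_prior=0.2,
        coupling_child_prior=0.2,
        coupling_self=0.2,
        session_topic_sd=1.5,
        topic_persistence=0.6,
        parent_persistence=0.0,
        parent_routine=0.9,
        responsive_fraction=0.45,
        cs_initial_roots=200,
        cs_root_growth=0.0,
        cs_initial_patterns=110,
        cs_pattern_growth=0.0,
    )
    cond.update(overrides)
    return SimParams(**cond)


def null_params(**overrides) -> SimParams:
    """The type-I-error condition: every adaptation channel switched off.

    Same scale and session structure as :func:`recovery_params`, but all
    cross-speaker couplings, the child's self-persistence and the
    parent's expansion response are zero, so any rejection of a
    coupling term in the density models is a false positive.
    """
    cond = dict(
        coupling_parent_current=0.0,
        coupling_child_current=0.0,
        coupling_parent_prior=0.0,
        coupling_child_prior=0.0,
        coupling_self=0.0,
        expansion_gain=0.0,
        session_topic_sd=1.5,
        topic_persistence=0.6,
        parent_persistence=0.0,
        parent_routine=0.9,
        responsive_fraction=0.45,
        cs_initial_roots=200,
        cs_root_growth=0.0,
        cs_initial_patterns=110,
        cs_pattern_growth=0.0,
    )
    cond.update(overrides)
    return SimParams(**cond)


@dataclass
class GroundTruth:
    """Parameters and realized per-session statistics of one simulation."""

    params: SimParams
    seed: int
    expected_signs: dict
    session_stats: pd.DataFrame  # session, age, tokens/density/types per speaker
    qal_token_share: float

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "params": self.params.to_dict(),
                "seed": self.seed,
                "expected_signs": self.expected_signs,
                "qal_token_share": self.qal_token_share,
                "session_stats": self.session_stats.to_dict(orient="records"),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc)
        return doc


def _root_labels(n: int) -> list[str]:
    """Deterministic synthetic tri-literal root labels (c1-c2-c3)."""
    labels = []
    k = len(_CONSONANTS)
    i = 0
    while len(labels) < n:
        a, rem = divmod(i, k * k)
        b, c = divmod(rem, k)
        if a != b and b != c:  # adjacent identical radicals are unrealistic
            labels.append("-".join((_CONSONANTS[a], _CONSONANTS[b], _CONSONANTS[c])))
        i += 1
    return labels[:n]


def _quota_primary_binyans(weights: np.ndarray, shares: dict) -> np.ndarray:
    """Assign a primary binyan per root so token shares track the mixture.

    Greedy largest-deficit assignment in rank order keeps the realized
    weighted share of each binyan close to its target even though the
    head roots carry a large fraction of the token mass.
    """
    names = list(shares)
    target = np.array([shares[b] for b in names], dtype=float)
    w = weights / weights.sum()
    acc = np.zeros(len(names))
    cum = 0.0
    out = np.empty(len(w), dtype=int)
    for i in range(len(w)):
        cum += w[i]
        deficit = target * cum - acc
        j = int(np.argmax(deficit))
        out[i] = j
        acc[j] += w[i]
    return out


def _pool_feature(counts: np.ndarray) -> np.ndarray:
    """Log empirical share of a usage-count vector, smoothed for zeros.

    A coupling coefficient ``b`` multiplies a construct's sampling
    weight by ``(share + eps)**b`` of the coupled stratum - a
    log-linear opinion pool between the speaker's base distribution and
    the partner's empirical distribution.  Because a uniform boost
    cancels in the softmax, only the *shape* of the partner's usage
    (its concentration) transfers, never its token volume, and the
    geometric pooling cannot run away however often it is iterated.
    An all-zero vector (nothing observed yet) contributes nothing.
    """
    total = counts.sum()
    if total <= 0:
        return np.zeros_like(counts, dtype=float)
    eps = 0.5 / total
    return np.log(counts / total + eps)


class _Lexicon:
    """Static sampling structures shared by both strata."""

    def __init__(self, params: SimParams):
        self.params = params
        self.root_labels = _root_labels(params.cds_n_roots)
        ranks = np.arange(1, params.cds_n_roots + 1, dtype=float)
        self.root_w = (ranks + params.root_zipf_offset) ** -params.root_zipf_exponent
        self.root_w /= self.root_w.sum()
        self.binyan_names = list(params.binyan_shares)
        self.binyan_p = np.array(
            [params.binyan_shares[b] for b in self.binyan_names], dtype=float
        )
        self.primary = _quota_primary_binyans(self.root_w, params.binyan_shares)
        self.qal_index = (
            self.binyan_names.index("Qal") if "Qal" in self.binyan_names else 0
        )

        # global inflected-pattern list with per-binyan index blocks
        self.patterns = inv.full_inflection_inventory()
        self.pattern_fields = [
            (
                ip.pattern.binyan.value,
                ip.pattern.temporal.value,
                str(ip.agreement.person) if ip.agreement.person else "",
                ip.agreement.number or "",
                ip.agreement.gender or "",
            )
            for ip in self.patterns
        ]
        self.by_binyan: dict[str, np.ndarray] = {}
        pattern_w = np.zeros(len(self.patterns))
        for b in self.binyan_names:
            idx = np.array(
                [i for i, ip in enumerate(self.patterns) if ip.pattern.binyan.value == b]
            )
            self.by_binyan[b] = idx
            w = np.arange(1, len(idx) + 1, dtype=float) ** -params.pattern_zipf_exponent
            pattern_w[idx] = params.binyan_shares[b] * w / w.sum()
        self.pattern_w = pattern_w  # stationary marginal over all 167 categories
        # child acquisition order: frequent-first over the global marginal
        self.pattern_rank = np.argsort(-pattern_w, kind="stable")


def _stratified_root_sample(
    lex: _Lexicon,
    rng,
    logw: np.ndarray,
    support: np.ndarray,
    size: int,
) -> np.ndarray:
    """Sample roots from softmax(logw) within a support set, stratified by
    primary-binyan class.

    The number of tokens drawn from Qal-primary roots is binomial at the
    *base* class share, so persistence and adaptation boosts redistribute
    mass within a binyan class but can never drift the realized binyan
    mixture away from its calibrated share.
    """
    is_qal = lex.primary[support] == lex.qal_index
    sup_q, sup_o = support[is_qal], support[~is_qal]
    if sup_q.size == 0 or sup_o.size == 0:
        lw = logw[support]
        p = np.exp(lw - lw.max())
        p /= p.sum()
        return rng.choice(support, size=size, p=p)
    base = lex.root_w[support].sum()
    n_q = rng.binomial(size, lex.root_w[sup_q].sum() / base)
    parts = []
    for idx, k in ((sup_q, n_q), (sup_o, size - n_q)):
        lw = logw[idx]
        p = np.exp(lw - lw.max())
        p /= p.sum()
        parts.append(rng.choice(idx, size=k, p=p))
    return np.concatenate(parts)


def _sample_binyans(lex: _Lexicon, roots: np.ndarray, rng) -> np.ndarray:
    prim = lex.primary[roots]
    flip = rng.random(roots.size) < lex.params.binyan_mix_noise
    if flip.any():
        prim = prim.copy()
        prim[flip] = rng.choice(len(lex.binyan_names), size=int(flip.sum()), p=lex.binyan_p)
    return prim


def _sample_patterns(
    lex: _Lexicon,
    binyans: np.ndarray,
    logit_bonus: np.ndarray,
    known: Optional[np.ndarray],
    rng,
    temp: float = 1.0,
) -> np.ndarray:
    """Sample one global pattern index per token given its binyan.

    ``logit_bonus`` is a length-167 additive log-weight vector;
    ``known`` restricts the child to acquired categories (falling back
    to the binyan's full inventory when none is acquired yet); ``temp``
    > 1 flattens the distribution (parent breadth expansion).
    """
    out = np.empty(binyans.size, dtype=int)
    for b_idx in np.unique(binyans):
        name = lex.binyan_names[b_idx]
        mask = binyans == b_idx
        idx = lex.by_binyan[name]
        if known is not None:
            acquired = idx[np.isin(idx, known)]
            if acquired.size:
                idx = acquired
        logw = (np.log(lex.pattern_w[idx]) + logit_bonus[idx]) / temp
        p = np.exp(logw - logw.max())
        p /= p.sum()
        out[mask] = rng.choice(idx, size=int(mask.sum()), p=p)
    return out


def _negbin(rng, mean: float, k: float) -> int:
    p = k / (k + mean)
    return max(1, int(rng.negative_binomial(k, p)))


def _density(root_idx: np.ndarray, pat_idx: np.ndarray) -> tuple[float, int, int]:
    links = set(zip(root_idx.tolist(), pat_idx.tolist()))
    n = len(set(root_idx.tolist())) + len(set(pat_idx.tolist()))
    m = len(links)
    if n < 2:
        return float("nan"), n, m
    return m / (n * (n - 1) / 2), n, m


def simulate_dyad(
    params: Optional[SimParams] = None, seed: Optional[int] = None
) -> tuple[CorpusTable, GroundTruth]:
    """Generate one coded dyadic corpus plus its ground truth.

    Within each session the parent first produces a base batch of
    tokens (coupled to the child's previous session), the child then
    produces its tokens (coupled to its own previous session and to the
    parent's current base batch), and the parent finally produces a
    responsive batch coupled to the child's current tokens.
    Bit-reproducible given (params, seed).
    """
    params = params or SimParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    lex = _Lexicon(params)
    n_pat = len(lex.patterns)
    n_roots = params.cds_n_roots

    ages = np.linspace(params.age_start_days, params.age_end_days, params.n_sessions)
    ages = np.round(ages).astype(int)

    child_prev_root = np.zeros(n_roots)
    child_prev_pat = np.zeros(n_pat)
    parent_prev_root = np.zeros(n_roots)
    parent_prev_pat = np.zeros(n_pat)
    child_density_ema: Optional[float] = None
    topic_state: Optional[np.ndarray] = None
    prev_par_tokens: Optional[tuple] = None

    counts: dict[tuple, int] = {}
    stats_rows = []
    qal_tokens = 0
    all_tokens = 0

    for s in range(1, params.n_sessions + 1):
        n_cds = _negbin(rng, params.cds_tokens_mean, params.token_dispersion)
        n_cs = _negbin(rng, params.cs_tokens_mean, params.token_dispersion)
        n_resp = int(round(n_cds * params.responsive_fraction))
        n_base = n_cds - n_resp

        # breadth expansion when the child's recent networks were dense
        # (low growth potential): flatten the parent's pattern logits
        temp = 1.0
        if child_density_ema is not None and stats_rows:
            prev_d = stats_rows[-1]["density_cs"]
            if np.isfinite(prev_d) and prev_d > child_density_ema:
                temp = 1.0 + params.expansion_gain * (prev_d - child_density_ema) / max(
                    child_density_ema, 1e-9
                )

        # --- parent base batch (coupled to child at N-1) ---
        # conversation-topic noise: session activities modulate the common,
        # concrete head vocabulary (the region a toddler can track), while
        # the long tail of rare roots stays at its stationary frequency
        n_topical = min(n_roots, params.topic_head_roots)
        rho = params.topic_persistence
        innov = rng.normal(0.0, params.session_topic_sd, size=n_topical)
        if topic_state is None:
            topic_state = innov
        else:
            topic_state = rho * topic_state + np.sqrt(1.0 - rho**2) * innov
        topic = np.zeros(n_roots)
        topic[:n_topical] = topic_state
        root_logw = (
            np.log(lex.root_w)
            + topic
            + params.parent_routine * _pool_feature(parent_prev_root)
            + params.coupling_child_prior * _pool_feature(child_prev_root)
        )
        all_roots = np.arange(n_roots)
        # lexical priming: a parent token re-uses one of the parent's own
        # previous-session wordforms with probability 1 - exp(-b), which
        # lengthens activity runs without collapsing breadth
        pi_pp = 1.0 - np.exp(-params.parent_persistence)
        n_prime = rng.binomial(n_base, pi_pp) if prev_par_tokens is not None else 0
        if n_prime:
            primed = rng.integers(0, prev_par_tokens[0].size, size=n_prime)
            prime_roots = prev_par_tokens[0][primed]
            prime_pats = prev_par_tokens[1][primed]
        else:
            prime_roots = np.empty(0, dtype=int)
            prime_pats = np.empty(0, dtype=int)
        n_fresh = n_base - n_prime
        fresh_roots = _stratified_root_sample(lex, rng, root_logw, all_roots, n_fresh)
        fresh_bin = _sample_binyans(lex, fresh_roots, rng)
        pat_bonus = params.parent_routine * _pool_feature(
            parent_prev_pat
        ) + params.coupling_child_prior * _pool_feature(child_prev_pat)
        fresh_pats = _sample_patterns(lex, fresh_bin, pat_bonus, None, rng, temp=temp)
        par_roots_a = np.concatenate([prime_roots, fresh_roots])
        par_pats_a = np.concatenate([prime_pats, fresh_pats])

        par_cur_root = np.bincount(par_roots_a, minlength=n_roots).astype(float)
        par_cur_pat = np.bincount(par_pats_a, minlength=n_pat).astype(float)

        # --- child (growing inventory, coupled to parent current + both priors) ---
        k_roots = min(n_roots, int(round(params.cs_initial_roots + params.cs_root_growth * (s - 1))))
        k_pats = int(round(params.cs_initial_patterns + params.cs_pattern_growth * (s - 1)))
        known_roots = np.arange(k_roots)
        known_pats = lex.pattern_rank[: min(n_pat, k_pats)]

        bonus_r = (
            params.coupling_self * _pool_feature(child_prev_root)
            + params.coupling_parent_current * _pool_feature(par_cur_root)
            + params.coupling_parent_prior * _pool_feature(parent_prev_root)
        )
        child_logw = np.log(lex.root_w) + bonus_r
        bonus_p = (
            params.coupling_self * _pool_feature(child_prev_pat)
            + params.coupling_parent_current * _pool_feature(par_cur_pat)
            + params.coupling_parent_prior * _pool_feature(parent_prev_pat)
        )
        # current-session attunement as token re-use: with probability
        # 1 - exp(-b) a child token re-uses a wordform the parent just
        # produced (restricted to the child's inventory), so the parent's
        # realized wordform concentration transfers link-for-link
        known_pat_mask = np.zeros(n_pat, dtype=bool)
        known_pat_mask[known_pats] = True
        reusable = np.flatnonzero((par_roots_a < k_roots) & known_pat_mask[par_pats_a])
        pi_pc = 1.0 - np.exp(-params.coupling_parent_current)
        n_copy = rng.binomial(n_cs, pi_pc) if reusable.size else 0
        picked = rng.choice(reusable, size=n_copy) if n_copy else np.empty(0, dtype=int)
        n_own = n_cs - n_copy
        own_roots = _stratified_root_sample(lex, rng, child_logw, known_roots, n_own)
        own_bin = _sample_binyans(lex, own_roots, rng)
        own_pats = _sample_patterns(lex, own_bin, bonus_p, known_pats, rng)
        chi_roots = np.concatenate([par_roots_a[picked], own_roots])
        chi_pats = np.concatenate([par_pats_a[picked], own_pats])

        chi_root_counts = np.bincount(chi_roots, minlength=n_roots).astype(float)
        chi_pat_counts = np.bincount(chi_pats, minlength=n_pat).astype(float)

        # --- parent responsive batch (coupled to child current) ---
        # mirror image of the child's attunement: a responsive parent
        # token re-uses one of the child's current wordforms with
        # probability 1 - exp(-b), else follows the parent's own base
        if n_resp > 0:
            pi_cc = 1.0 - np.exp(-params.coupling_child_current)
            n_copy_b = rng.binomial(n_resp, pi_cc) if chi_roots.size else 0
            picked_b = (
                rng.integers(0, chi_roots.size, size=n_copy_b)
                if n_copy_b
                else np.empty(0, dtype=int)
            )
            n_own_b = n_resp - n_copy_b
            par_roots_b = _stratified_root_sample(lex, rng, root_logw, all_roots, n_own_b)
            par_bin_b = _sample_binyans(lex, par_roots_b, rng)
            par_pats_b = _sample_patterns(lex, par_bin_b, pat_bonus, None, rng, temp=temp)
            par_roots_b = np.concatenate([chi_roots[picked_b], par_roots_b])
            par_pats_b = np.concatenate([chi_pats[picked_b], par_pats_b])
        else:
            par_roots_b = np.empty(0, dtype=int)
            par_pats_b = np.empty(0, dtype=int)

        par_roots = np.concatenate([par_roots_a, par_roots_b])
        par_pats = np.concatenate([par_pats_a, par_pats_b])

        # --- bookkeeping ---
        for speaker, roots_, pats_ in (("CDS", par_roots, par_pats), ("CS", chi_roots, chi_pats)):
            for r, pt in zip(roots_.tolist(), pats_.tolist()):
                key = (speaker, s, int(r), int(pt))
                counts[key] = counts.get(key, 0) + 1
            qal_tokens += sum(
                1 for pt in pats_.tolist() if lex.pattern_fields[pt][0] == "Qal"
            )
            all_tokens += len(pats_)

        d_cs, n_cs_nodes, m_cs = _density(chi_roots, chi_pats)
        d_cds, n_cds_nodes, m_cds = _density(par_roots, par_pats)
        stats_rows.append(
            {
                "session_index": s,
                "age_days": int(ages[s - 1]),
                "tokens_cs": int(chi_roots.size),
                "tokens_cds": int(par_roots.size),
                "density_cs": d_cs,
                "density_cds": d_cds,
                "n_cs": n_cs_nodes,
                "m_cs": m_cs,
                "n_cds": n_cds_nodes,
                "m_cds": m_cds,
            }
        )
        if np.isfinite(d_cs):
            child_density_ema = (
                d_cs
                if child_density_ema is None
                else 0.7 * child_density_ema + 0.3 * d_cs
            )

        child_prev_root = chi_root_counts
        child_prev_pat = chi_pat_counts
        parent_prev_root = np.bincount(par_roots, minlength=n_roots).astype(float)
        parent_prev_pat = np.bincount(par_pats, minlength=n_pat).astype(float)
        prev_par_tokens = (par_roots, par_pats)

    records = []
    for (speaker, s, r, pt), c in sorted(counts.items()):
        binyan, temporal, person, number, gender = lex.pattern_fields[pt]
        records.append(
            {
                "dyad_id": params.dyad_id,
                "session_index": s,
                "age_days": int(ages[s - 1]),
                "speaker": speaker,
                "root": lex.root_labels[r],
                "binyan": binyan,
                "temporal": temporal,
                "person": person,
                "number": number,
                "gender": gender,
                "count": c,
            }
        )
    table = from_records(
        records,
        provenance={"generator": "morphnet.simulate", "seed": int(seed)},
    )
    truth = GroundTruth(
        params=params,
        seed=int(seed),
        expected_signs=_expected_signs(params),
        session_stats=pd.DataFrame(stats_rows),
        qal_token_share=qal_tokens / all_tokens if all_tokens else float("nan"),
    )
    return table, truth


def _sign(x: float) -> str:
    return "positive" if x > 0 else ("zero" if x == 0 else "negative")


def _expected_signs(params: SimParams) -> dict:
    """Ground-truth coupling signs, keyed 'model->predictor'."""
    return {
        "density.cs->density.cds": _sign(params.coupling_parent_current),
        "density.cs->prior.density.cds": _sign(params.coupling_parent_prior),
        "density.cds->density.cs": _sign(params.coupling_child_current),
        "density.cds->prior.density.cs": _sign(params.coupling_child_prior),
    }


#: Predictors of the density models that carry a simulated coupling.
COUPLING_TERMS: tuple[tuple[str, str], ...] = (
    ("density.cs", "density.cds"),
    ("density.cs", "prior.density.cds"),
    ("density.cds", "density.cs"),
    ("density.cds", "prior.density.cs"),
)


@dataclass
class RecoveryReport:
    """Replicated simulate->analyze->fit results for the density models."""

    n_reps: int
    params: SimParams
    expected_signs: dict
    raw: pd.DataFrame  # rep, model, predictor, estimate, p
    summary: pd.DataFrame  # per (model, predictor) rates

    def rate(self, model: str, predictor: str, column: str) -> float:
        row = self.summary[
            (self.summary["model"] == model) & (self.summary["predictor"] == predictor)
        ]
        return float(row[column].iloc[0])

    def false_positive_rate(self, alpha: float = 0.05) -> float:
        """Pooled rejection rate over coupling terms with zero true coupling."""
        zero_terms = [
            (m, p)
            for (m, p) in COUPLING_TERMS
            if self.expected_signs[f"{m}->{p}"] == "zero"
        ]
        if not zero_terms:
            raise ValueError("no zero-coupling terms under these parameters")
        mask = self.raw.apply(
            lambda r: (r["model"], r["predictor"]) in zero_terms, axis=1
        )
        return float((self.raw[mask]["p"] < alpha).mean())

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "n_reps": self.n_reps,
                "expected_signs": self.expected_signs,
                "summary": self.summary.to_dict(orient="records"),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc)
        return doc


def recovery_experiment(
    params: Optional[SimParams] = None,
    n_reps: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Simulate -> measure -> fit the density models, ``n_reps`` times.

    Each replicate runs the full pipeline (corpus, per-session bipartite
    networks, density series, lagged OLS fits for ``density.cs`` and
    ``density.cds``) and records every coefficient.  The summary reports
    per-predictor sign and significance rates against the generator's
    ground-truth coupling signs.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    params = params or recovery_params()
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    rows = []
    for rep, rs in enumerate(rep_seeds):
        table, _ = simulate_dyad(params, seed=int(rs))
        series = build_network_series(table, params.dyad_id)
        measures = measure_table(series, include_centrality=False)
        frame = assemble_network_frame(measures)
        for response in ("density.cs", "density.cds"):
            fit = fit_density_lm(frame, response)
            for name, prow in fit.params.iterrows():
                rows.append(
                    {
                        "rep": rep,
                        "model": response,
                        "predictor": name,
                        "estimate": float(prow["estimate"]),
                        "p": float(prow["p"]),
                    }
                )
    raw = pd.DataFrame(rows)
    expected = _expected_signs(params)
    summary_rows = []
    for (model, pred), grp in raw.groupby(["model", "predictor"], sort=True):
        pos = grp["estimate"] > 0
        sig = grp["p"] < alpha
        key = f"{model}->{pred}"
        want = expected.get(key)
        if want == "positive":
            recovered = (pos & sig).mean()
        elif want == "negative":
            recovered = (~pos & sig).mean()
        else:
            recovered = np.nan
        summary_rows.append(
            {
                "model": model,
                "predictor": pred,
                "mean_estimate": float(grp["estimate"].mean()),
                "positive_rate": float(pos.mean()),
                "significant_rate": float(sig.mean()),
                "positive_and_significant_rate": float((pos & sig).mean()),
                "sign_recovery_rate": float(recovered) if recovered == recovered else np.nan,
            }
        )
    return RecoveryReport(
        n_reps=n_reps,
        params=params,
        expected_signs=expected,
        raw=raw,
        summary=pd.DataFrame(summary_rows),
    )
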