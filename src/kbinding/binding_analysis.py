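"""Binder calling, k-binding stratification, cross-reactivity test and logos.

Definitions: for a universe U of seven peptide-MHC targets, a variant is
*S-binding* when it binds exactly the targets in S (and none in U - S) and
*k-binding* when |S| = k.  Binders are called from panning data by presence
in the final MACS round of both replicates; the k = 0 stratum consists of
observed variants that bind nothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_space import CANONICAL_AA, POSITIONS


# ---------------------------------------------------------------------------
# binder calling and profiles
# ---------------------------------------------------------------------------

def call_binders(
    panning: pd.DataFrame,
    target: str,
    min_reads: int = 1,
    final_round: int | None = None,
    replicates: Sequence[int] = (1, 2),
) -> Set[str]:
    """Variants binding ``target``: >= min_reads in the final round of every replicate.

    The default ``min_reads=1`` is a presence call.  Raises if a required
    (target, replicate, round) slice is absent from the table.
    """
    sub = panning[panning["target"] == target]
    if final_round is None:
        if len(sub) == 0:
            raise ValueError(f"no panning data for target {target!r}")
        final_round = int(sub["round"].max())
    per_rep: List[Set[str]] = []
    for rep in replicates:
        slab = sub[(sub["replicate"] == rep) & (sub["round"] == final_round)]
        if len(slab) == 0:
            raise ValueError(
                f"missing panning data for (target={target!r}, "
                f"replicate={rep}, round={final_round})"
            )
        keep = slab[slab["reads"] >= min_reads]
        per_rep.append(set(keep["cdr3_alpha"].str.cat(keep["cdr3_beta"])))
    out = per_rep[0]
    for s in per_rep[1:]:
        out &= s
    return out


def observed_universe(panning: pd.DataFrame) -> List[str]:
    """All distinct variants observed anywhere in the dataset, sorted."""
    seqs = panning["cdr3_alpha"].str.cat(panning["cdr3_beta"])
    return sorted(set(seqs))


def profile_variants(
    binder_sets: Mapping[str, Set[str]],
    universe_variants: Iterable[str],
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variant 7-bit binding profiles with S and k over the target universe.

    Returns a table with one row per universe variant: ``cdr3_alpha``,
    ``cdr3_beta``, one boolean column per target, and ``k`` (the number of
    bound targets).  Variants bound to no target form the k = 0 stratum.
    """
    targets = list(targets) if targets is not None else list(binder_sets)
    missing = [t for t in targets if t not in binder_sets]
    if missing:
        raise ValueError(f"binder sets missing for targets: {missing}")
    seqs = sorted(set(universe_variants))
    df = pd.DataFrame(
        {"cdr3_alpha": [s[:3] for s in seqs], "cdr3_beta": [s[3:] for s in seqs]}
    )
    bound = np.zeros((len(seqs), len(targets)), dtype=bool)
    for ti, t in enumerate(targets):
        bset = binder_sets[t]
        bound[:, ti] = [s in bset for s in seqs]
    for ti, t in enumerate(targets):
        df[t] = bound[:, ti]
    df["k"] = bound.sum(axis=1).astype(int)
    return df


def stratum_counts(profiles: pd.DataFrame, n_targets: int = 7) -> Dict[int, int]:
    """n_k for k = 0..n_targets; sums to the number of profiled variants."""
    vc = profiles["k"].value_counts()
    return {k: int(vc.get(k, 0)) for k in range(n_targets + 1)}


def binding_sets(profiles: pd.DataFrame, targets: Sequence[str]) -> pd.Series:
    """Per-variant frozenset S of bound targets."""
    bound = profiles[list(targets)].to_numpy(dtype=bool)
    t = np.array(targets, dtype=object)
    return pd.Series(
        [frozenset(t[row]) for row in bound], index=profiles.index, name="S"
    )


# ---------------------------------------------------------------------------
# cross-reactivity binomial test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossReactivityTest:
    """One-sided binomial test of excess multi-target binding."""

    n_universe: int
    observed_multi: int  # variants with k >= 2
    null_rate: float  # P(k >= 2) under independent per-target binding
    pvalue: float


def multi_binding_null_rate(per_target_rates: Sequence[float]) -> float:
    """P(k >= 2) under independent Bernoulli binding, by exact enumeration.

    Enumerates the full 2^T outcome lattice, so the result is exact for the
    seven-target universe (128 outcomes).
    """
    p = np.asarray(per_target_rates, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("per-target rates must lie in [0, 1]")
    q = 0.0
    for outcome in itertools.product((0, 1), repeat=len(p)):
        if sum(outcome) >= 2:
            prob = 1.0
            for b, pt in zip(outcome, p):
                prob *= pt if b else (1.0 - pt)
            q += prob
    return float(q)


def crossreactivity_binomial_test(
    strata: Mapping[int, int], per_target_rates: Sequence[float]
) -> CrossReactivityTest:
    """Upper-tail binomial test: do more variants bind >= 2 targets than chance?

    The null is independent per-target Bernoulli binding at the supplied
    empirical marginal rates; success probability P(k >= 2) is computed
    exactly over the outcome lattice, and the exact binomial upper tail is
    evaluated for the observed count of multi-binding variants among all
    ``n_universe`` profiled variants.
    """
    n = int(sum(strata.values()))
    observed = int(sum(v for k, v in strata.items() if k >= 2))
    qrate = multi_binding_null_rate(per_target_rates)
    if qrate == 0.0:
        pval = 0.0 if observed > 0 else 1.0
    else:
        pval = float(stats.binom.sf(observed - 1, n, qrate))
    return CrossReactivityTest(n, observed, qrate, pval)


# ---------------------------------------------------------------------------
# sequence logos
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogoMatrix:
    """Position frequency matrix with per-position information content (bits)."""

    freq: pd.DataFrame  # index = position names, columns = residues
    info: pd.Series  # bits per position
    n_sequences: float
    basis: int

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out["information_bits"] = self.info
        out.to_csv(path, sep="\t", index_label="position")


def build_logo(
    variants: Sequence[str],
    basis: int = 20,
    weights: Sequence[float] | None = None,
) -> LogoMatrix:
    """Per-position residue frequencies and information content for 6-mers.

    Information content follows the WebLogo convention
    ``IC_p = log2(basis) - H_p`` with ``H_p`` the Shannon entropy (bits) of
    the position's residue frequencies; ``basis`` defaults to 20 (the
    canonical protein alphabet) and can be set to 19 for the library
    alphabet.  ``weights`` (e.g. read counts) weight the sequences.
    """
    variants = list(variants)
    if not variants:
        raise ValueError("cannot build a logo from an empty sequence list")
    w = np.ones(len(variants)) if weights is None else np.asarray(weights, float)
    if w.shape != (len(variants),) or (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be nonnegative with positive sum")
    letters = list(CANONICAL_AA)
    counts = np.zeros((len(POSITIONS), len(letters)))
    lut = {aa: i for i, aa in enumerate(letters)}
    for seq, wi in zip(variants, w):
        for pi, aa in enumerate(seq):
            counts[pi, lut[aa]] += wi
    freq = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.log2(basis) - entropy
    return LogoMatrix(
        freq=pd.DataFrame(freq, index=list(POSITIONS), columns=letters),
        info=pd.Series(info, index=list(POSITIONS), name="bits"),
        n_sequences=float(w.sum()),
        basis=basis,
    )


def logo_grid(
    profiles: pd.DataFrame,
    targets: Sequence[str],
    max_k: int = 2,
    basis: int = 20,
) -> Dict[FrozenSet[str], LogoMatrix]:
    """One logo per nonempty S-binding class with 1 <= |S| <= max_k.

    For seven targets and max_k = 2 there are at most C(7,1) + C(7,2) = 28
    classes; empty classes are simply absent from the result.
    """
    S = binding_sets(profiles, targets)
    seqs = profiles["cdr3_alpha"].str.cat(profiles["cdr3_beta"])
    out: Dict[FrozenSet[str], LogoMatrix] = {}
    for k in range(1, max_k + 1):
        for combo in itertools.combinations(targets, k):
            key = frozenset(combo)
            members = seqs[S == key]
            if len(members):
                out[key] = build_logo(list(members), basis=basis)
    return out


def round_logos(
    panning: pd.DataFrame, target: str, replicate: int, basis: int = 20
) -> Dict[int, LogoMatrix]:
    """Read-weighted logo per panning round for one (target, replicate)."""
    sub = panning[(panning["target"] == target) & (panning["replicate"] == replicate)]
    out = {}
    for rnd, grp in sub.groupby("round", observed=True):
        seqs = grp["cdr3_alpha"].str.cat(grp["cdr3_beta"])
        out[int(rnd)] = build_logo(
            list(seqs), basis=basis, weights=grp["reads"].to_numpy(float)
        )
    return out


# ---------------------------------------------------------------------------
# panning-progression diagnostics
# ---------------------------------------------------------------------------

def panning_diagnostics(panning: pd.DataFrame, top_n: int = 100) -> pd.DataFrame:
    """Unique-variant counts and top-N read shares per (target, replicate, round).

    Enrichment across MACS rounds shows up as decreasing unique-variant
    counts and increasing top-100 read share.  Ties at rank ``top_n`` are
    broken by lexicographic variant order, making the share deterministic.
    """
    rows = []
    for (target, rep, rnd), grp in panning.groupby(
        ["target", "replicate", "round"], observed=True
    ):
        grp = grp[grp["reads"] > 0]
        total = grp["reads"].sum()
        ordered = grp.sort_values(
            ["reads", "cdr3_alpha", "cdr3_beta"], ascending=[False, True, True]
        )
        top = ordered["reads"].head(top_n).sum()
        rows.append(
            {
                "target": target,
                "replicate": rep,
                "round": rnd,
                "n_unique": int(len(grp)),
                "total_reads": int(total),
                f"top{top_n}_share": float(top / total) if total else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values(["target", "replicate", "round"]).reset_index(
        drop=True
    )
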