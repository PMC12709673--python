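"""Ground-truth binding landscapes and simulated panning read-count data.

The raw selection data behind the analysis is a yeast-display library of
~19**6 CDR3 variants panned for three MACS rounds, in duplicate, against seven
related peptide-MHC targets.  This module generates datasets with the same
statistical structure so every downstream stage (binder calling, k-binding
stratification, classifier training, masking importance) can be exercised and
validated against a known ground truth.

Model
-----
A :class:`Landscape` assigns each variant ``v`` and target ``t`` an affinity

    affinity(v, t) = sum_p  w_p * BLOSUM50(v[p], consensus_t[p])

where ``w_p`` are per-position importance weights (the generator's ground
truth for the residue-importance analyses) and ``consensus_t`` is the
target's preferred 6-mer.  A variant truly binds ``t`` when its affinity
(plus optional Gaussian noise) reaches the target's threshold.  All targets
share the alpha-chain consensus (the dominant "DSW" motif), so cross-
reactivity is motif-driven, while the beta consensi differ, giving each
target its own specific binders.

Panning is simulated as a latent-abundance chain: round-0 abundance is
uniform over the sampled library; each MACS round multiplies abundance by
``exp(sharpness * (affinity - threshold))`` (floored at a small nonspecific
leak), renormalizes, and sequencing draws ``depth`` reads multinomially.
Replicates share the latent chain but draw reads independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequence_space import (
    Alphabet,
    POSITIONS,
    TCRVariant,
    blosum50_scheme,
    make_alphabet,
)

#: Default names of the seven peptide-MHC targets.
DEFAULT_TARGETS: Tuple[str, ...] = ("Tax", "HUD", "BENE", "F", "TY", "TM", "HOM")

#: Columns of a panning table.
PANNING_COLUMNS = ("target", "replicate", "round", "cdr3_alpha", "cdr3_beta", "reads")

_CALIBRATION_SEED = 987_654_321  # fixed stream for threshold calibration
_CALIBRATION_N = 200_000


@dataclass(frozen=True)
class Landscape:
    """Ground-truth binding rule over the 6-position variant space."""

    targets: Tuple[str, ...]
    consensus: Dict[str, str]  # target -> 6-mer
    position_weights: Dict[str, float]  # position name -> weight >= 0
    thresholds: Dict[str, float]  # target -> binding threshold
    noise_sd: float = 0.0
    alphabet: Alphabet = field(default_factory=make_alphabet)

    def __post_init__(self) -> None:
        if len(self.targets) != len(set(self.targets)):
            raise ValueError("duplicate target names")
        for t in self.targets:
            if len(self.consensus[t]) != len(POSITIONS):
                raise ValueError(f"consensus for {t} must cover all 6 positions")
        missing = [p for p in POSITIONS if p not in self.position_weights]
        if missing:
            raise ValueError(f"position_weights missing {missing}")
        if any(w < 0 for w in self.position_weights.values()):
            raise ValueError("position weights must be nonnegative")

    # -- residue coding -------------------------------------------------
    def encode(self, seqs: Sequence[str]) -> np.ndarray:
        """Map sequences to (n, 6) alphabet-index codes."""
        lut = {aa: i for i, aa in enumerate(self.alphabet.letters)}
        return np.array([[lut[aa] for aa in s] for s in seqs], dtype=np.int16)

    def decode(self, codes: np.ndarray) -> List[str]:
        letters = np.array(list(self.alphabet.letters))
        return ["".join(row) for row in letters[codes]]

    def _contrib(self) -> np.ndarray:
        """(n_targets, 6, |A|) per-position per-letter affinity contributions."""
        scheme = blosum50_scheme()
        sim = {
            aa: {bb: scheme.lookup[aa][i] for i, bb in enumerate("ARNDCQEGHILKMFPSTWYV")}
            for aa in "ARNDCQEGHILKMFPSTWYV"
        }
        out = np.zeros((len(self.targets), len(POSITIONS), self.alphabet.size))
        for ti, t in enumerate(self.targets):
            for pi, p in enumerate(POSITIONS):
                w = self.position_weights[p]
                cons = self.consensus[t][pi]
                for ai, aa in enumerate(self.alphabet.letters):
                    out[ti, pi, ai] = w * sim[aa][cons]
        return out

    # -- affinity and binding -------------------------------------------
    def affinity_matrix(self, seqs: Sequence[str]) -> np.ndarray:
        """(n, n_targets) affinities for a batch of 6-mer sequences."""
        codes = self.encode(seqs)
        contrib = self._contrib()
        n = len(seqs)
        out = np.zeros((n, len(self.targets)))
        for pi in range(len(POSITIONS)):
            out += contrib[:, pi, :][:, codes[:, pi]].T
        return out

    def affinity(self, variant: TCRVariant | str, target: str) -> float:
        seq = variant.sequence if isinstance(variant, TCRVariant) else variant
        ti = self.targets.index(target)
        return float(self.affinity_matrix([seq])[0, ti])

    def true_binding(
        self,
        variant: TCRVariant | str,
        target: str,
        rng: np.random.Generator | None = None,
    ) -> bool:
        """Whether the variant truly binds the target.

        With ``noise_sd > 0`` a Gaussian perturbation is added to the affinity
        before thresholding (an ``rng`` is then required); with ``noise_sd ==
        0`` the call is deterministic.
        """
        a = self.affinity(variant, target)
        if self.noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            a = a + rng.normal(0.0, self.noise_sd)
        return bool(a >= self.thresholds[target])

    # -- serialization --------------------------------------------------
    def to_yaml(self, path) -> None:
        """Write the landscape as a structured config file."""
        import yaml

        payload = {
            "targets": list(self.targets),
            "consensus": dict(self.consensus),
            "position_weights": dict(self.position_weights),
            "thresholds": dict(self.thresholds),
            "noise_sd": float(self.noise_sd),
            "excluded_residue": next(
                aa for aa in "ARNDCQEGHILKMFPSTWYV" if aa not in self.alphabet.letters
            ),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Landscape":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            targets=tuple(d["targets"]),
            consensus=d["consensus"],
            position_weights=d["position_weights"],
            thresholds=d["thresholds"],
            noise_sd=d.get("noise_sd", 0.0),
            alphabet=make_alphabet(d.get("excluded_residue", "C")),
        )

    def ground_truth_profiles(self, seqs: Sequence[str]) -> pd.DataFrame:
        """Noise-free per-variant binding profile table (7 booleans + k)."""
        aff = self.affinity_matrix(seqs)
        thr = np.array([self.thresholds[t] for t in self.targets])
        bound = aff >= thr
        df = pd.DataFrame(
            {
                "cdr3_alpha": [s[:3] for s in seqs],
                "cdr3_beta": [s[3:] for s in seqs],
            }
        )
        for ti, t in enumerate(self.targets):
            df[t] = bound[:, ti]
        df["k"] = bound.sum(axis=1).astype(int)
        return df


def export_ground_truth(landscape: Landscape, seqs: Sequence[str], path) -> pd.DataFrame:
    """Write the noise-free BindingProfile table for ``seqs`` as TSV."""
    df = landscape.ground_truth_profiles(seqs)
    df.to_csv(path, sep="\t", index=False)
    return df


def default_landscape(
    binding_rate: float = 0.05,
    noise_sd: float = 0.0,
    alphabet: Alphabet | None = None,
) -> Landscape:
    """The default seven-target landscape used throughout the analysis.

    All targets share the alpha consensus ``DSW`` (the dominant cross-reactive
    motif); beta consensi are related hydrophobic triplets that differentiate
    the targets.  Position weights follow the strict importance hierarchy
    a99 > a101 > b98 > a100 > b100 > b99.  Thresholds are calibrated, on a
    fixed internal random stream, to the (1 - binding_rate) quantile of the
    affinity distribution over uniformly drawn variants, so each target's
    marginal binding probability is approximately ``binding_rate``.
    """
    alphabet = alphabet or make_alphabet()
    # Beta consensi are mutually dissimilar triplets (mostly non-positive
    # BLOSUM50 cross-similarities), so the beta chain carries target
    # specificity while the shared alpha motif drives cross-reactivity; the
    # resulting k-binding counts decay with k apart from a high-k excess of
    # strong shared-motif variants.
    beta_consensus = {
        "Tax": "WAK",
        "HUD": "PSE",
        "BENE": "GTQ",
        "F": "RVD",
        "TY": "FIH",
        "TM": "YLN",
        "HOM": "MNG",
    }
    consensus = {t: "DSW" + beta_consensus[t] for t in DEFAULT_TARGETS}
    # Strict importance hierarchy.  Values are chosen jointly with the
    # consensus letters so the per-position information (weight x the
    # decisiveness of the consensus residue's BLOSUM50 column) follows the
    # same ordering: the W column is ~2x more decisive than the D column,
    # so a101 carries a much smaller raw weight than a99.
    weights = {
        "a99": 1.0,
        "a100": 0.28,
        "a101": 0.40,
        "b98": 0.35,
        "b99": 0.12,
        "b100": 0.20,
    }
    land = Landscape(
        targets=DEFAULT_TARGETS,
        consensus=consensus,
        position_weights=weights,
        thresholds={t: 0.0 for t in DEFAULT_TARGETS},
        noise_sd=noise_sd,
        alphabet=alphabet,
    )
    rng = np.random.default_rng(_CALIBRATION_SEED)
    codes = rng.integers(0, alphabet.size, size=(_CALIBRATION_N, len(POSITIONS)))
    seqs = land.decode(codes)
    aff = land.affinity_matrix(seqs)
    thresholds = {
        t: float(np.quantile(aff[:, ti], 1.0 - binding_rate))
        for ti, t in enumerate(land.targets)
    }
    return replace(land, thresholds=thresholds)


@dataclass(frozen=True)
class SimConfig:
    """Scale and enrichment parameters of a panning simulation."""

    n_variants: int = 200_000
    depth: int = 1_000_000
    n_rounds: int = 3
    enrichment_sharpness: float = 0.3
    leak: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.depth < 1 or self.n_rounds < 1:
            raise ValueError("n_variants, depth and n_rounds must be >= 1")


def sample_library(landscape: Landscape, n_variants: int, rng: np.random.Generator) -> List[str]:
    """Draw ``n_variants`` distinct variants uniformly from the 19**6 space."""
    size = landscape.alphabet.size
    space = size ** len(POSITIONS)
    if n_variants > space:
        raise ValueError("n_variants exceeds library diversity")
    codes = np.array([], dtype=np.int64)
    while codes.size < n_variants:
        extra = rng.integers(0, space, size=int(1.1 * (n_variants - codes.size)) + 16)
        codes = np.unique(np.concatenate([codes, extra]))
    codes = codes[:n_variants]
    digits = np.empty((n_variants, len(POSITIONS)), dtype=np.int16)
    rem = codes.copy()
    for pi in range(len(POSITIONS) - 1, -1, -1):
        digits[:, pi] = rem % size
        rem //= size
    return landscape.decode(digits)


def simulate_panning(
    landscape: Landscape,
    config: SimConfig,
    n_replicates: int = 2,
    variants: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate multi-round panning for every (target, replicate).

    Returns a long-format table with columns ``target, replicate, round,
    cdr3_alpha, cdr3_beta, reads`` containing only observed (reads > 0) rows;
    each (target, replicate, round) has read total exactly ``config.depth``.
    Round 0 is the unselected input library.  Bit-reproducible for a given
    ``config.seed``.  An explicit ``variants`` list overrides the uniform
    library draw (useful for planting known binders).
    """
    master = np.random.SeedSequence(config.seed)
    lib_rng = np.random.default_rng(master.spawn(1)[0])
    if variants is None:
        seqs = sample_library(landscape, config.n_variants, lib_rng)
    else:
        seqs = list(variants)
    aff = landscape.affinity_matrix(seqs)
    thr = np.array([landscape.thresholds[t] for t in landscape.targets])
    # Enrichment factor per variant per target, floored at the leak rate.
    factors = np.maximum(
        np.exp(config.enrichment_sharpness * (aff - thr)), config.leak
    )

    alphas = np.array([s[:3] for s in seqs])
    betas = np.array([s[3:] for s in seqs])
    children = master.spawn(1 + len(landscape.targets) * n_replicates)[1:]

    frames = []
    ci = 0
    for ti, target in enumerate(landscape.targets):
        for rep in range(1, n_replicates + 1):
            rng = np.random.default_rng(children[ci])
            ci += 1
            abundance = np.full(len(seqs), 1.0 / len(seqs))
            for rnd in range(config.n_rounds + 1):
                reads = rng.multinomial(config.depth, abundance)
                nz = reads > 0
                frames.append(
                    pd.DataFrame(
                        {
                            "target": target,
                            "replicate": rep,
                            "round": rnd,
                            "cdr3_alpha": alphas[nz],
                            "cdr3_beta": betas[nz],
                            "reads": reads[nz],
                        }
                    )
                )
                if rnd < config.n_rounds:
                    abundance = abundance * factors[:, ti]
                    abundance /= abundance.sum()
    out = pd.concat(frames, ignore_index=True)
    out["target"] = out["target"].astype("category")
    return out


def validate_panning(table: pd.DataFrame) -> pd.DataFrame:
    """Check panning-table schema and value constraints; return the table."""
    missing = [c for c in PANNING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"panning table missing columns: {missing}")
    if (table["reads"] < 0).any():
        raise ValueError("negative read counts in panning table")
    return table
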