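"""Residue/chain-masked training importance and interface-energy correlation.

Masking deletes one residue (a99, a100, a101, b98, b99, b100) or a whole
chain (alpha, beta) from every training and validation sequence — eight mask
configurations in total — without telling the model which positions were
removed.  Retraining on each masked dataset and measuring the change in
held-out F1/AUPRC relative to the full-sequence model (Delta = masked -
full; negative means deterioration) ranks the positions by marginal
importance.

The mean per-mask Delta-F1 can additionally be correlated (Spearman) with an
externally computed table of interface-energy changes after alanine
substitution (median Delta I_sc per mask, lower = more stable), linking the
sequence-level importance ranking to structural energetics.  That energy
table is a consumed input; no structural modeling happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ModelConfig
from .evaluation import (
    StatResult,
    assign_folds,
    cross_validate,
    paired_and_unpaired_tests,
)
from .sequence_space import MASK_LABELS, POSITIONS, EmbeddingScheme, get_scheme

#: Mask label -> 0-based positions deleted from the 6-mer.
MASK_POSITIONS: Dict[str, Tuple[int, ...]] = {
    **{p: (i,) for i, p in enumerate(POSITIONS)},
    "alpha": (0, 1, 2),
    "beta": (3, 4, 5),
}

RESIDUE_MASKS: Tuple[str, ...] = POSITIONS
CHAIN_MASKS: Tuple[str, ...] = ("alpha", "beta")


def mask_sequence(seq: str, mask: str) -> str:
    try:
        drop = MASK_POSITIONS[mask]
    except KeyError:
        raise ValueError(
            f"unknown mask label {mask!r}; expected one of {MASK_LABELS}"
        ) from None
    return "".join(aa for i, aa in enumerate(seq) if i not in drop)


def mask_dataset(profiles: pd.DataFrame, mask: str) -> pd.DataFrame:
    """Delete the masked residue(s) from every variant; keep all rows.

    The masked table stores the shortened sequence in ``masked_seq``.  After
    masking, distinct variants can collapse onto the same shortened sequence
    while carrying different binding profiles; such conflicting duplicates
    are intentionally all retained (no deduplication), so the row count is
    preserved.
    """
    out = profiles.copy()
    seqs = out["cdr3_alpha"].str.cat(out["cdr3_beta"])
    out["masked_seq"] = [mask_sequence(s, mask) for s in seqs]
    return out


@dataclass
class ImportanceResult:
    """Per-cell metric deltas for all masks plus the derived residue ranking."""

    results: pd.DataFrame  # cross_validate rows incl. mask == "full"
    deltas: pd.DataFrame  # per (mask, seed, fold, stratum, target): delta_f1/auprc
    ranking: List[str]  # the 6 residue masks, most important first
    mean_delta_f1: Dict[str, float]
    mean_delta_auprc: Dict[str, float]
    chain_test: StatResult  # alpha vs beta paired Wilcoxon on delta-F1


def masked_importance(
    profiles: pd.DataFrame,
    targets: Sequence[str],
    scheme: EmbeddingScheme | str,
    config: ModelConfig,
    n_folds: int = 10,
    n_seed_reps: int = 2,
    base_seed: int = 0,
    masks: Sequence[str] = MASK_LABELS,
    folds_to_run: Sequence[int] | None = None,
) -> ImportanceResult:
    """Retrain under each mask on identical folds and rank residues by Delta-F1.

    Fold partitions and seeds are fixed once and reused for the full model
    and every mask, so deltas are paired cell-by-cell.  Residues are ranked
    by mean Delta-F1 over all per-stratum and per-target cells (most
    negative = most important); ties break lexicographically on the label.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    folds = {
        base_seed
        + rep: assign_folds(
            profiles["k"].to_numpy(), n_folds, np.random.default_rng(base_seed + rep)
        )
        for rep in range(n_seed_reps)
    }
    common = dict(
        targets=targets,
        scheme=scheme,
        config=config,
        n_folds=n_folds,
        n_seed_reps=n_seed_reps,
        base_seed=base_seed,
        fold_assignments=folds,
        folds_to_run=folds_to_run,
    )
    full = cross_validate(profiles, **common)
    full["mask"] = "full"
    frames = [full]
    for mask in masks:
        res = cross_validate(
            mask_dataset(profiles, mask), sequence_column="masked_seq", **common
        )
        res["mask"] = mask
        frames.append(res)
    results = pd.concat(frames, ignore_index=True)

    keys = ["seed", "fold", "stratum", "target"]
    cells = results[~((results["stratum"] == "all") & (results["target"].isin(["all", "all_macro"])))]
    base = cells[cells["mask"] == "full"].set_index(keys)[["f1", "auprc"]]
    deltas = []
    for mask in masks:
        cur = cells[cells["mask"] == mask].set_index(keys)[["f1", "auprc"]]
        d = cur.join(base, lsuffix="_masked", rsuffix="_full")
        d["delta_f1"] = d["f1_masked"] - d["f1_full"]
        d["delta_auprc"] = d["auprc_masked"] - d["auprc_full"]
        d["mask"] = mask
        deltas.append(d.reset_index())
    delta_df = pd.concat(deltas, ignore_index=True)

    mean_f1 = {
        m: float(delta_df.loc[delta_df["mask"] == m, "delta_f1"].mean()) for m in masks
    }
    mean_ap = {
        m: float(delta_df.loc[delta_df["mask"] == m, "delta_auprc"].mean())
        for m in masks
    }
    residue_masks = [m for m in masks if m in RESIDUE_MASKS]
    ranking = sorted(residue_masks, key=lambda m: (mean_f1[m], m))

    if "alpha" in masks and "beta" in masks:
        a = delta_df[delta_df["mask"] == "alpha"].set_index(keys)["delta_f1"]
        b = delta_df[delta_df["mask"] == "beta"].set_index(keys)["delta_f1"]
        joined = pd.concat([a, b], axis=1, keys=["alpha", "beta"]).dropna()
        chain = paired_and_unpaired_tests(
            joined["alpha"], joined["beta"], kind="wilcoxon_signed_rank", alternative="less"
        )
    else:
        chain = StatResult("wilcoxon-signed-rank", np.nan, np.nan)

    return ImportanceResult(results, delta_df, ranking, mean_f1, mean_ap, chain)


# ---------------------------------------------------------------------------
# interface-energy correlation
# ---------------------------------------------------------------------------

def read_energy_table(path) -> pd.DataFrame:
    """Read a mask -> Delta I_sc TSV (columns ``mask``, ``delta_isc``)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"mask", "delta_isc"} - set(df.columns)
    if missing:
        raise ValueError(f"energy table missing columns: {sorted(missing)}")
    unknown = set(df["mask"]) - set(MASK_LABELS) - {"WT"}
    if unknown:
        raise ValueError(f"unknown mask labels in energy table: {sorted(unknown)}")
    return df[df["mask"] != "WT"].reset_index(drop=True)


def correlate_energy(
    mean_deltas: Mapping[str, float], energies: pd.DataFrame
) -> StatResult:
    """Spearman correlation between per-mask metric deltas and Delta I_sc.

    Computed over mask labels present in both tables (at least 3 required).
    With tie-degenerate input (all energies equal) the correlation is
    reported as 0 with p = 1.
    """
    etab = energies.set_index("mask")["delta_isc"]
    shared = sorted(set(mean_deltas) & set(etab.index))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared mask labels to correlate, got {len(shared)}"
        )
    x = np.array([mean_deltas[m] for m in shared], dtype=float)
    y = etab.loc[shared].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult("spearman", 0.0, 1.0)
    rho, p = stats.spearmanr(x, y)
    return StatResult("spearman", float(rho), float(p))
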