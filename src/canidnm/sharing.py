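"""Sibling-shared mutation analysis.

Early embryonic mutations in a parent can enter several gametes and so
recur in multiple offspring of the same parents.  Shared groups are
DNMs observed at the same position with the same alternate allele in
two or more offspring that share at least one parent; the full-sibling
pair-based shared fraction estimates the early-mutation load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SharedMutationSummary:
    """Shared-group table and the full-sib pair-based sharing fraction."""

    groups: pd.DataFrame  # contig, pos, alt, members, relation, phases
    pair_table: pd.DataFrame  # pair, n_shared, n_unique
    total_unique: int
    total_shared: int
    fraction: float
    n_excluded_unrelated: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("sharing fraction outside [0, 1]")


def _relation(offspring_a, offspring_b, parents: dict) -> str:
    pa, pb = parents[offspring_a], parents[offspring_b]
    shared = set(pa) & set(pb)
    if pa == pb:
        return "full_sib"
    if shared:
        return "half_sib"
    return "unrelated"


def find_shared_mutations(dnms: pd.DataFrame, pedigree: dict) -> SharedMutationSummary:
    """Group recurrent DNMs and compute the full-sib sharing fraction.

    Parameters
    ----------
    dnms : DataFrame
        Columns ``trio_id``/``offspring_id``, ``contig``, ``pos``,
        ``alt`` and optionally ``phase``.
    pedigree : dict
        offspring_id -> (sire_id, dam_id); also accepts trio ids as
        keys when the DNM table carries trio ids.

    Mutations sharing (contig, pos, alt) across two or more offspring
    form a group; the relation label comes from shared parents, and
    groups whose members share no parent are flagged unrelated and
    excluded from the sharing fraction.  The fraction is pair-based:
    total shared over total unique mutations across all full-sib pairs.
    """
    dnms = dnms.copy()
    id_col = "offspring_id" if "offspring_id" in dnms.columns else "trio_id"
    groups = []
    n_unrelated = 0
    shared_keys = set()
    for (contig, pos, alt), grp in dnms.groupby(["contig", "pos", "alt"]):
        members = sorted(grp[id_col].unique())
        if len(members) < 2:
            continue
        rels = {
            _relation(a, b, pedigree)
            for i, a in enumerate(members)
            for b in members[i + 1:]
        }
        if rels == {"unrelated"}:
            relation = "RECURRENT_UNRELATED"
            n_unrelated += 1
        elif "half_sib" in rels or "unrelated" in rels:
            relation = "half_sib"
        else:
            relation = "full_sib"
        phases = sorted(grp["phase"].unique()) if "phase" in grp.columns else []
        groups.append(
            {
                "contig": contig,
                "pos": pos,
                "alt": alt,
                "members": ",".join(map(str, members)),
                "n_members": len(members),
                "relation": relation,
                "phases": ",".join(map(str, phases)),
            }
        )
        if relation != "RECURRENT_UNRELATED":
            shared_keys.add((contig, pos, alt))
    group_df = pd.DataFrame(
        groups,
        columns=["contig", "pos", "alt", "members", "n_members", "relation", "phases"],
    )

    # full-sib pairs and their per-pair shared / unique mutation counts
    by_offspring = {
        oid: set(map(tuple, sub[["contig", "pos", "alt"]].itertuples(index=False)))
        for oid, sub in dnms.groupby(id_col)
    }
    offspring = sorted(by_offspring)
    pair_rows = []
    for i, a in enumerate(offspring):
        for b in offspring[i + 1:]:
            if _relation(a, b, pedigree) != "full_sib":
                continue
            sa, sb = by_offspring[a], by_offspring[b]
            pair_rows.append(
                {
                    "pair": f"{a}|{b}",
                    "n_shared": len(sa & sb),
                    "n_unique": len(sa | sb),
                }
            )
    pair_table = pd.DataFrame(pair_rows, columns=["pair", "n_shared", "n_unique"])
    total_shared = int(pair_table["n_shared"].sum()) if len(pair_table) else 0
    total_unique = int(pair_table["n_unique"].sum()) if len(pair_table) else 0
    fraction = total_shared / total_unique if total_unique else 0.0
    return SharedMutationSummary(
        groups=group_df,
        pair_table=pair_table,
        total_unique=total_unique,
        total_shared=total_shared,
        fraction=fraction,
        n_excluded_unrelated=n_unrelated,
    )


def shared_fraction_bootstrap(
    summary: SharedMutationSummary, n_boot: int = 1000, seed: int | None = None
):
    """Bootstrap the pair-based sharing fraction over full-sib pairs.

    Resamples pairs with replacement ``n_boot`` times and returns
    (point fraction, (ci_low, ci_high)) with percentile 95% bounds.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducible bootstrap")
    pairs = summary.pair_table
    if len(pairs) == 0:
        raise ValueError("no full-sib pairs to bootstrap")
    shared = pairs["n_shared"].to_numpy(dtype=float)
    unique = pairs["n_unique"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pairs), size=(n_boot, len(pairs)))
    num = shared[idx].sum(axis=1)
    den = unique[idx].sum(axis=1)
    frac = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    lo, hi = np.percentile(frac, [2.5, 97.5])
    return summary.fraction, (float(lo), float(hi))
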