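"""Per-pair, per-direction pathway enrichment (Fisher exact + BH-FDR).

For each decoded pair and each direction ('-' decreased, '+'
increased) every pathway is tested for over-representation of the
pair's differential genes with a two-sided Fisher exact test on the
2x2 table (in pathway x differential in direction), over the universe
of analyzed genes.  P-values are Benjamini-Hochberg adjusted, by
default within each pair across all pathway x direction tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .data_io import ValidationError
from .hmm import StateDecoding


@dataclass
class PathwayCollection:
    """pathway_id -> (name, gene set)."""

    pathways: dict[str, tuple[str, frozenset]]

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {pid} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def items(self):
        return self.pathways.items()


def read_gmt(path) -> PathwayCollection:
    """Read gene sets from GMT (id <tab> description <tab> genes...)."""
    pathways = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pid, name, genes = parts[0], parts[1], frozenset(g for g in parts[2:] if g)
            if pid in pathways:
                raise ValidationError(f"duplicate pathway id {pid}")
            pathways[pid] = (name, genes)
    return PathwayCollection(pathways)


def write_gmt(pathways: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, (name, genes) in pathways.items():
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


def fisher_pvalue(table, alternative: str = "two-sided") -> float:
    """Fisher exact p for one 2x2 table (the engine behind all
    enrichment and set-overlap tests in this package)."""
    return float(stats.fisher_exact(np.asarray(table), alternative=alternative)[1])


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    decoding: StateDecoding,
    pathways: PathwayCollection,
    universe,
    alternative: str = "two-sided",
    adjust: bool = True,
) -> pd.DataFrame:
    """Enrichment rows (pathway x direction) for one decoded pair.

    Columns: pair_id, pathway_id, direction, k (differential genes in
    pathway), K (pathway size in universe), n (differential genes),
    N (universe size), odds_ratio (conditional MLE), p and, when
    *adjust*, q (BH across all rows of this pair).  Pathways with no
    gene in the universe are omitted.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    genes = np.asarray(decoding.gene_ids)
    in_universe = np.isin(genes, list(universe))
    genes, states = genes[in_universe], decoding.states[in_universe]
    N = len(genes)
    rows = []
    for direction in ("-", "+"):
        diff = set(genes[states == direction])
        n = len(diff)
        for pid, (name, pgenes) in pathways.items():
            pset = pgenes & universe
            K = len(pset)
            if K == 0:
                continue
            k = len(pset & diff)
            table = np.array([[k, K - k], [n - k, N - K - (n - k)]])
            p = fisher_pvalue(table, alternative=alternative)
            orr = _odds_ratio(table, kind="conditional").statistic
            rows.append(
                {
                    "pair_id": decoding.pair_id,
                    "pathway_id": pid,
                    "pathway": name,
                    "direction": direction,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "odds_ratio": float(orr),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def enrich_all_pairs(
    decodings: list[StateDecoding],
    pathways: PathwayCollection,
    universe,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    scope: str = "per_pair",
) -> pd.DataFrame:
    """Enrichment table across all pairs with a ``significant`` flag.

    ``scope`` controls the BH adjustment: ``"per_pair"`` (default)
    adjusts within each pair, ``"global"`` across the whole table.
    """
    if scope not in ("per_pair", "global"):
        raise ValidationError(f"unknown adjustment scope {scope!r}")
    frames = [
        fisher_enrichment(d, pathways, universe, alternative, adjust=(scope == "per_pair"))
        for d in decodings
    ]
    out = pd.concat(frames, ignore_index=True)
    if scope == "global":
        out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
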