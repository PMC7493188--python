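"""Consensus ranking of docking models by contact conservation.

Given an ensemble of n models of the same complex, each intermolecular
residue contact (k, l) has a conservation rate

    CR_kl = (# models containing the contact) / n,

ranging from 1/n (seen once) to 1 (seen in every model).  A model i with
M_i contacts receives the raw score

    S_i = sum of CR_kl over its contacts,

and the normalized score S̄_i = S_i / M_i by which models are ranked: a
model scores highly when its interface is built from the contacts most
frequently realized across the ensemble.  The normalized score of the
top-ranked model — the Maxscore — measures how sharp the consensus is and
predicts whether consensus scoring is reliable for the ensemble.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import Contact, ContactMap

__all__ = [
    "ConservationMap",
    "RankEntry",
    "Ranking",
    "conservation_rates",
    "consrank_score",
    "rank_models",
    "conserved_contacts_above",
    "export_consensus_map",
]


@dataclass(frozen=True)
class ConservationMap:
    """Per-contact conservation rates over an ensemble of size n."""

    n: int
    rate: Mapping[Contact, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("consensus undefined for fewer than 2 models")


@dataclass(frozen=True)
class RankEntry:
    model_id: str
    S: float
    M: int
    S_norm: float
    rank: int


@dataclass(frozen=True)
class Ranking:
    """Models in descending normalized-score order."""

    entries: tuple[RankEntry, ...]

    @property
    def maxscore(self) -> float:
        """Normalized score of the top-ranked model (consensus sharpness)."""
        return self.entries[0].S_norm

    def top(self, k: int) -> tuple[RankEntry, ...]:
        return self.entries[:k]

    def entry(self, model_id: str) -> RankEntry:
        for e in self.entries:
            if e.model_id == model_id:
                return e
        raise KeyError(model_id)

    def to_tsv(self) -> str:
        lines = ["rank\tmodel_id\tS_norm\tS\tM"]
        for e in self.entries:
            lines.append(f"{e.rank}\t{e.model_id}\t{e.S_norm:.6f}\t{e.S:.6f}\t{e.M}")
        return "\n".join(lines) + "\n"


def conservation_rates(maps: Sequence[ContactMap]) -> ConservationMap:
    """Conservation rate of every contact observed in at least one model."""
    n = len(maps)
    if n < 2:
        raise ValueError("consensus undefined for fewer than 2 models")
    counts: Counter[Contact] = Counter()
    for m in maps:
        counts.update(m.contacts)
    return ConservationMap(n=n, rate={c: k / n for c, k in counts.items()})


def consrank_score(cmap: ContactMap, rates: ConservationMap) -> tuple[float, float]:
    """Raw and normalized consensus score of one model.

    Contacts absent from the rates table (possible when scoring an external
    model against a fixed ensemble) contribute 0 to S but count in M.
    """
    if cmap.M == 0:
        raise ValueError(f"{cmap.model_id}: zero contacts (should have been filtered)")
    S = float(sum(rates.rate.get(c, 0.0) for c in cmap.contacts))
    return S, S / cmap.M


def rank_models(maps: Sequence[ContactMap], rates: ConservationMap) -> Ranking:
    """Total ordering by normalized score, descending.

    Ties are broken by contact count M descending (richer interface
    preferred), then model_id ascending, making the order deterministic
    and independent of input order.
    """
    scored = []
    for cmap in maps:
        S, S_norm = consrank_score(cmap, rates)
        scored.append((cmap.model_id, S, cmap.M, S_norm))
    scored.sort(key=lambda t: (-t[3], -t[2], t[0]))
    entries = tuple(
        RankEntry(model_id=mid, S=S, M=M, S_norm=S_norm, rank=i + 1)
        for i, (mid, S, M, S_norm) in enumerate(scored)
    )
    return Ranking(entries=entries)


def conserved_contacts_above(
    rates: ConservationMap, threshold: float
) -> list[tuple[Contact, float]]:
    """Contacts with conservation rate strictly above a threshold.

    Sorted by rate descending, then by contact key for determinism.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    hits = [(c, r) for c, r in rates.rate.items() if r > threshold]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


def export_consensus_map(
    rates: ConservationMap,
    shape: tuple[int, int] | None = None,
    annotate: Iterable[str] = (),
    maps: Sequence[ContactMap] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Dense consensus contact map plus a per-contact table.

    The matrix has one row per residue position of the first partner and
    one column per position of the second partner, holding the conservation
    rate of each contact (0 where no contact was ever observed) — the
    numeric form of the gray-scale consensus maps used to judge consensus
    sharpness visually.  ``annotate`` marks the contacts of the named
    models in extra boolean table columns (the models must be in ``maps``).
    """
    annotate = list(annotate)
    by_id = {m.model_id: m for m in (maps or [])}
    for mid in annotate:
        if mid not in by_id:
            raise ValueError(f"annotated model {mid!r} not in ensemble")

    contacts = sorted(rates.rate)
    if shape is None:
        n1 = max((c[0][1] for c in contacts), default=0)
        n2 = max((c[1][1] for c in contacts), default=0)
        shape = (n1, n2)
    matrix = np.zeros(shape, dtype=float)
    rows = []
    for c in contacts:
        (ch1, r1), (ch2, r2) = c
        if 1 <= r1 <= shape[0] and 1 <= r2 <= shape[1]:
            matrix[r1 - 1, r2 - 1] = rates.rate[c]
        row = {
            "chain1": ch1,
            "res1": r1,
            "chain2": ch2,
            "res2": r2,
            "rate": rates.rate[c],
        }
        for mid in annotate:
            row[f"in_{mid}"] = c in by_id[mid].contacts
        rows.append(row)
    table = pd.DataFrame(rows)
    return matrix, table
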