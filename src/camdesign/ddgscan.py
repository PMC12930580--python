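"""Two-state in-silico residue scanning.

For each mutable position the scanner enumerates substitutions to every
standard amino acid except glycine and proline, scores each mutant and the
wild type in both the active and the inactive receptor state with a
pluggable stability scorer, and computes the replicate-averaged two-state
stability change

    ΔΔG = ΔG(mutant_active) - ΔG(mutant_inactive),

with ΔG(state) = score(mutant, state) - score(wild type, state) paired per
replicate. Negative ΔΔG classifies a mutation as relatively stabilizing the
active state. Per position, the most stabilizing mutation is selected, plus
a second one when its ΔΔG is negative and within a similarity window of
the best.

The scorer contract ``score(state, sequence, replicate_index) -> float``
decouples the scan from any particular stability method: the synthetic
additive table from the toy module satisfies it, and a file adapter ingests
externally computed per-mutation scores (e.g. Rosetta cartesian ddG output
expressed per state and replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd

from .statecontacts import ACTIVE, INACTIVE

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Substitution targets never used: glycine and proline perturb the backbone.
EXCLUDED_AA = frozenset("GP")


class StabilityScorer(Protocol):
    """Deterministic-per-replicate stability scoring contract."""

    def score(self, state: str, sequence: str, replicate_index: int = 0
              ) -> float: ...


@dataclass
class MutationCandidate:
    """Per-substitution two-state ΔG replicates and the decision value."""

    position: int                 # 0-based sequence index
    wt_aa: str
    mutant_aa: str
    dg_active: np.ndarray         # per-replicate mutant - wild-type, active
    dg_inactive: np.ndarray

    def __post_init__(self):
        self.dg_active = np.asarray(self.dg_active, dtype=float)
        self.dg_inactive = np.asarray(self.dg_inactive, dtype=float)
        if self.dg_active.shape != self.dg_inactive.shape:
            raise ValueError("replicate arrays must have equal length")

    @property
    def n_replicates(self) -> int:
        return self.dg_active.shape[0]

    @property
    def ddg(self) -> float:
        return float(self.dg_active.mean() - self.dg_inactive.mean())

    @property
    def name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mutant_aa}"


@dataclass
class ScanReport:
    """All candidates, their classification, and per-position selections."""

    candidates: list
    delta_similar: float
    classifications: dict = field(default_factory=dict)  # name -> label
    selections: dict = field(default_factory=dict)       # position -> [cand]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "position": c.position, "wt": c.wt_aa, "mutant": c.mutant_aa,
            "ddg": c.ddg,
            "classification": self.classifications.get(c.name, ""),
            "selected": any(c is s for s in
                            self.selections.get(c.position, [])),
        } for c in self.candidates]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def enumerate_substitutions(wt: str) -> list:
    """Substitution targets for a wild-type residue: the standard amino
    acids minus glycine, proline and the wild type itself, sorted by
    one-letter code (17 targets unless wt is G or P, then 18)."""
    if wt not in STANDARD_AA:
        raise ValueError(f"nonstandard wild-type amino acid {wt!r}")
    return sorted(set(STANDARD_AA) - EXCLUDED_AA - {wt})


def compute_ddg(position: int, mutant_aa: str, wt_sequence: str,
                scorer: StabilityScorer, n_replicates: int = 3
                ) -> MutationCandidate:
    """Replicate-paired two-state ΔΔG of one substitution.

    Per replicate r and state: ΔG_state(r) = score(state, mutant, r) -
    score(state, wild type, r); the decision value is
    mean(ΔG_active) - mean(ΔG_inactive).
    """
    wt_aa = wt_sequence[position]
    if mutant_aa not in enumerate_substitutions(wt_aa):
        raise ValueError(
            f"{mutant_aa!r} is not an allowed substitution for {wt_aa!r} "
            f"at position {position}"
        )
    mut_sequence = wt_sequence[:position] + mutant_aa \
        + wt_sequence[position + 1:]
    dg = {ACTIVE: [], INACTIVE: []}
    for state in (ACTIVE, INACTIVE):
        for r in range(n_replicates):
            try:
                mut = scorer.score(state, mut_sequence, r)
                ref = scorer.score(state, wt_sequence, r)
            except Exception as exc:
                raise RuntimeError(
                    f"scorer failed for state {state!r}, replicate {r}: {exc}"
                ) from exc
            dg[state].append(mut - ref)
    return MutationCandidate(position=position, wt_aa=wt_aa,
                             mutant_aa=mutant_aa,
                             dg_active=np.array(dg[ACTIVE]),
                             dg_inactive=np.array(dg[INACTIVE]))


def scan_positions(positions, wt_sequence: str, scorer: StabilityScorer,
                   n_replicates: int = 3) -> list:
    """All substitution candidates over the given 0-based positions."""
    candidates = []
    for pos in positions:
        for aa in enumerate_substitutions(wt_sequence[pos]):
            candidates.append(compute_ddg(pos, aa, wt_sequence, scorer,
                                          n_replicates))
    return candidates


def classify_and_select(candidates: list, delta_similar: float = 0.5
                        ) -> ScanReport:
    """Classify candidates by ΔΔG sign and pick per-position selections.

    Per position: the minimum-ΔΔG candidate is selected iff its ΔΔG is
    negative; the second-lowest is additionally selected iff it is negative
    and within ``delta_similar`` of the minimum. Exact ties break by
    one-letter code.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    report = ScanReport(candidates=list(candidates),
                        delta_similar=delta_similar)
    by_pos: dict = {}
    for c in candidates:
        by_pos.setdefault(c.position, []).append(c)
        if c.ddg < 0:
            label = "stabilizes_active"
        elif c.ddg > 0:
            label = "stabilizes_inactive"
        else:
            label = "neutral"
        report.classifications[c.name] = label
    for pos, group in by_pos.items():
        ranked = sorted(group, key=lambda c: (c.ddg, c.mutant_aa))
        selected = []
        if ranked[0].ddg < 0:
            selected.append(ranked[0])
            if (len(ranked) > 1 and ranked[1].ddg < 0
                    and ranked[1].ddg - ranked[0].ddg <= delta_similar):
                selected.append(ranked[1])
        report.selections[pos] = selected
    return report


# ---------------------------------------------------------------------------
# Scorer adapters
# ---------------------------------------------------------------------------

class PrecomputedScorer:
    """Scorer over externally computed per-mutation stability changes.

    Expects a table with columns (position, wt, mutant, state, replicate,
    score) where ``score`` is the mutational ΔG in that state *relative to
    the wild type* (the convention of typical per-mutation ddG output);
    accordingly the wild-type sequence scores 0 in every state. Sequences
    differing from the wild type at more than one position are not
    representable in such a table and raise.
    """

    def __init__(self, wt_sequence: str, table: pd.DataFrame):
        self.wt_sequence = wt_sequence
        required = {"position", "wt", "mutant", "state", "replicate", "score"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"score table lacks columns {sorted(missing)}")
        self._scores = {
            (int(r.position), r.mutant, r.state, int(r.replicate)):
                float(r.score)
            for r in table.itertuples()
        }

    @classmethod
    def from_tsv(cls, wt_sequence: str, path) -> "PrecomputedScorer":
        return cls(wt_sequence, pd.read_csv(path, sep="\t"))

    def score(self, state: str, sequence: str, replicate_index: int = 0
              ) -> float:
        diffs = [(i, aa) for i, (aa, wt) in
                 enumerate(zip(sequence, self.wt_sequence)) if aa != wt]
        if not diffs:
            return 0.0
        if len(diffs) > 1:
            raise ValueError(
                "precomputed tables cover single mutants only; sequence "
                f"differs from wild type at positions "
                f"{[i for i, _ in diffs]}"
            )
        pos, aa = diffs[0]
        key = (pos, aa, state, replicate_index)
        if key not in self._scores:
            raise KeyError(
                f"no precomputed score for position {pos}, mutant {aa!r}, "
                f"state {state!r}, replicate {replicate_index}"
            )
        return self._scores[key]
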