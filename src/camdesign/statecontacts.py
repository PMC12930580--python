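"""State-exclusive contact analysis on active/inactive structure ensembles.

Given ensembles of receptor structures labelled ``active`` or ``inactive``,
this module computes per-state residue contact frequencies, filters contacts
that are exclusive to one state (by default the inactive one — the contacts a
constitutive-activity design seeks to disrupt), and turns the residues of
those contacts into a mutable-position list after removing functionally
critical microswitch residues.

Residue identifiers are arbitrary sortable keys (integers for synthetic
systems, receptor residue numbers for real ones). A contact is defined as a
minimum heavy-atom distance below a cutoff (default 4.5 length units, the
same cutoff used by the dynamic-network module), with sequence-adjacent
pairs excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Contact cutoff shared by this module, the network module and the fixture
#: generators, in length units ("angstrom-equivalent" for toy systems).
CONTACT_CUTOFF = 4.5

ACTIVE = "active"
INACTIVE = "inactive"
STATES = (ACTIVE, INACTIVE)

ResidueId = Hashable


def residue_sort_key(residue):
    """Stable ordering over mixed residue ids: numeric before string."""
    if isinstance(residue, (int, float, np.integer, np.floating)):
        return (0, float(residue), "")
    return (1, 0.0, repr(residue))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """One structure: residue id -> (n_atoms, 3) heavy-atom coordinates."""

    identifier: str
    state: str
    residues: dict

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(
                f"state must be one of {STATES}, got {self.state!r}"
            )
        self.residues = {
            r: np.atleast_2d(np.asarray(xyz, dtype=float))
            for r, xyz in self.residues.items()
        }


@dataclass
class StructureEnsemble:
    """A set of structures sharing (at least partially) a residue indexing.

    If members disagree on residue ids, the intersection is used and the
    discrepancy is logged. A member sharing no residues with the rest is an
    error.
    """

    members: list

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must contain at least one member")
        shared = set(self.members[0].residues)
        union = set(self.members[0].residues)
        for m in self.members[1:]:
            shared &= set(m.residues)
            union |= set(m.residues)
        if not shared:
            bad = ", ".join(m.identifier for m in self.members)
            raise ValueError(
                f"no residues shared across ensemble members: {bad}"
            )
        if shared != union:
            logger.warning(
                "ensemble members disagree on residue indexing; using the "
                "%d shared residues (union has %d)", len(shared), len(union)
            )
        self.shared_residues = sorted(shared, key=residue_sort_key)

    def members_in_state(self, state: str) -> list:
        return [m for m in self.members if m.state == state]


@dataclass
class ContactTable:
    """Residue-pair -> (freq_active, freq_inactive), plus the settings used."""

    frequencies: dict
    cutoff: float = CONTACT_CUTOFF
    exclude_adjacent: bool = True
    n_members: dict = field(default_factory=dict)

    def pairs(self):
        return sorted(self.frequencies, key=lambda p: tuple(map(residue_sort_key, p)))


@dataclass
class ExclusiveContactSet:
    """Contacts present only in the target state, with their frequencies."""

    target_state: str
    pairs: list  # [(pair, freq_active, freq_inactive), ...]
    presence_min: float = 0.5
    absence_max: float = 0.0

    def residues(self) -> list:
        seen: list = []
        for (a, b), _, _ in self.pairs:
            for r in (a, b):
                if r not in seen:
                    seen.append(r)
        return sorted(seen, key=residue_sort_key)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PositionSelection:
    """Mutable candidate positions and the excluded ones with reasons."""

    candidates: list
    excluded: dict  # residue -> reason tag
    warning: str | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _is_adjacent(a: ResidueId, b: ResidueId) -> bool:
    """Sequence adjacency |Δindex| <= 1 for integer-like residue ids."""
    try:
        return abs(int(a) - int(b)) <= 1
    except (TypeError, ValueError):
        return False


def _member_contacts(member: Structure, resids: Sequence[ResidueId],
                     cutoff: float, exclude_adjacent: bool) -> set:
    contacts = set()
    for i, a in enumerate(resids):
        xa = member.residues[a]
        for b in resids[i + 1:]:
            if exclude_adjacent and _is_adjacent(a, b):
                continue
            if cdist(xa, member.residues[b]).min() < cutoff:
                contacts.add((a, b))
    return contacts


def contact_frequencies(ensemble: StructureEnsemble,
                        cutoff: float = CONTACT_CUTOFF,
                        exclude_adjacent: bool = True) -> ContactTable:
    """Per-state contact frequencies over an active/inactive ensemble.

    A pair is in contact in a member iff the minimum heavy-atom distance is
    strictly below ``cutoff``; its frequency in a state is the fraction of
    that state's members in which it is in contact. Pairs never in contact
    in any member are omitted from the table.
    """
    n_members = {s: len(ensemble.members_in_state(s)) for s in STATES}
    for s, n in n_members.items():
        if n == 0:
            raise ValueError(f"ensemble has no members in state {s!r}")
    resids = ensemble.shared_residues
    counts: dict = {}
    for member in ensemble.members:
        for pair in _member_contacts(member, resids, cutoff, exclude_adjacent):
            c = counts.setdefault(pair, {ACTIVE: 0, INACTIVE: 0})
            c[member.state] += 1
    freqs = {
        pair: (c[ACTIVE] / n_members[ACTIVE], c[INACTIVE] / n_members[INACTIVE])
        for pair, c in counts.items()
    }
    return ContactTable(frequencies=freqs, cutoff=cutoff,
                        exclude_adjacent=exclude_adjacent, n_members=n_members)


def exclusive_contacts(table: ContactTable,
                       target_state: str = INACTIVE,
                       presence_min: float = 0.5,
                       absence_max: float = 0.0) -> ExclusiveContactSet:
    """Contacts frequent in the target state and (near-)absent in the other.

    Keeps pairs with target-state frequency >= ``presence_min`` and
    other-state frequency <= ``absence_max``, sorted by descending target
    frequency then residue pair.
    """
    if target_state not in STATES:
        raise ValueError(f"unknown state {target_state!r}")
    if not (0.0 <= absence_max < presence_min <= 1.0):
        raise ValueError(
            "thresholds must satisfy 0 <= absence_max < presence_min <= 1, "
            f"got presence_min={presence_min}, absence_max={absence_max}"
        )
    idx = STATES.index(target_state)
    hits = []
    for pair, (fa, fi) in table.frequencies.items():
        f = (fa, fi)
        if f[idx] >= presence_min and f[1 - idx] <= absence_max:
            hits.append((pair, fa, fi))
    hits.sort(key=lambda h: (-h[1 + idx], tuple(map(residue_sort_key, h[0]))))
    return ExclusiveContactSet(target_state=target_state, pairs=hits,
                               presence_min=presence_min,
                               absence_max=absence_max)


def select_positions(exclusive: ExclusiveContactSet,
                     exclusion_list: Mapping[ResidueId, str] | None = None,
                     ) -> PositionSelection:
    """Mutable positions: residues of the exclusive contacts minus exclusions.

    ``exclusion_list`` maps residue id -> reason tag (e.g. a microswitch
    membership). An all-excluded outcome is reported with a warning rather
    than an error.
    """
    exclusion_list = dict(exclusion_list or {})
    residues = exclusive.residues()
    candidates = [r for r in residues if r not in exclusion_list]
    excluded = {r: exclusion_list[r] for r in residues if r in exclusion_list}
    warning = None
    if residues and not candidates:
        warning = "all residues of the exclusive contacts were excluded"
        logger.warning(warning)
    return PositionSelection(candidates=candidates, excluded=excluded,
                             warning=warning)


# ---------------------------------------------------------------------------
# Worked-example data: dopamine D2/D3 receptor inactive-state contacts
# ---------------------------------------------------------------------------

#: Ballesteros-Weinstein labels for the fifteen D2R residues involved in the
#: twelve published inactive-state-exclusive contacts.
D2R_RESIDUE_LABELS = {
    48: "I48^1.46", 69: "T69^2.39", 73: "I73^2.43", 125: "L125^3.43",
    132: "R132^3.50", 166: "I166^4.56", 192: "Y192^5.41", 209: "Y209^5.58",
    368: "E368^6.30", 372: "T372^6.34", 376: "A376^6.38", 382: "F382^6.44",
    418: "N418^7.45", 419: "S419^7.46", 426: "Y426^7.53",
}

#: SYNTHETIC stand-in for the published table of twelve D2R/D3R
#: inactive-exclusive contact pairs. The individual pairings in the original
#: supplementary table are not publicly reproduced here; this reconstruction
#: keeps what is documented in the main text — exactly twelve pairs whose
#: residue union is the fifteen residues above, including the ionic-lock
#: (R132-E368) and Y-Y (Y209-Y426) microswitch pairs — so the downstream
#: position-selection worked example is exact. Do not treat the remaining
#: pairings as experimental.
D2R_INACTIVE_CONTACTS_SYNTHETIC = [
    (132, 368),   # ionic lock R3.50 - E6.30
    (209, 426),   # Y-Y motif Y5.58 - Y7.53
    (48, 418),
    (48, 419),
    (69, 132),
    (73, 372),
    (73, 376),
    (125, 372),
    (125, 382),
    (132, 372),
    (166, 192),
    (192, 382),
]

#: Microswitch residues excluded from mutagenesis to avoid loss of function.
D2R_MICROSWITCH_EXCLUSIONS = {
    132: "ionic lock (R3.50)",
    368: "ionic lock (E6.30)",
    382: "PIF motif (F6.44)",
    209: "Y-Y motif (Y5.58)",
    426: "Y-Y motif (Y7.53)",
}


def d2r_exclusive_contact_set() -> ExclusiveContactSet:
    """The D2R worked-example contacts as an :class:`ExclusiveContactSet`.

    Frequencies are the idealized (0 active, 1 inactive) of a perfectly
    state-exclusive contact; see ``D2R_INACTIVE_CONTACTS_SYNTHETIC`` for
    provenance caveats.
    """
    pairs = [(p, 0.0, 1.0) for p in D2R_INACTIVE_CONTACTS_SYNTHETIC]
    return ExclusiveContactSet(target_state=INACTIVE, pairs=pairs)
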