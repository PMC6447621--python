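"""Markov triplet paradigm: experiment designs and pseudorandom stimulus streams.

The paradigm presents a continuous, pause-free stream of sound triplets at a
300 ms inter-onset interval.  Each triplet consists of a two-sound *root*
(``AB`` or ``CD``, internal transition probability 1) followed by an *ending*
(``E`` or ``F``).  The root→ending transition probability is manipulated:
each root has a designated high-probability continuation (p = 0.9) and a
low-probability one (p = 0.1), while roots follow endings with a constant
p = 0.5.  Independently, each sound is played from a *standard* or *deviant*
loudspeaker side (endings: 80 % / 20 %; root sounds: 95 % / 5 %), crossing
statistical and physical deviance:

======================  =================  ================
ending                  standard location  deviant location
======================  =================  ================
high TP (p = 0.9)       STANDARD (0.72)    PHYS_DEV (0.18)
low TP (p = 0.1)        STAT_DEV (0.08)    DOUBLE_DEV (0.02)
======================  =================  ================

Category and location assignment uses exact counts (shuffling, not Bernoulli
draws), so the table's proportions hold exactly in every block.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EndingCategory",
    "ExperimentDesign",
    "FamiliarityTrial",
    "ParadigmError",
    "StreamEvent",
    "Triplet",
    "TripletSequence",
    "TransitionMatrix",
    "classify_ending",
    "generate_block",
    "insert_targets",
    "make_design",
    "make_familiarity_test",
    "transition_matrix",
    "validate_sequence",
]

ROLES = ("A", "B", "C", "D", "E", "F")
ROOTS = ("AB", "CD")
ENDINGS = ("E", "F")
#: designated high-probability continuation of each root (Fig. layout: ABE, CDF)
HIGH_ENDING = {"AB": "E", "CD": "F"}
LOW_ENDING = {"AB": "F", "CD": "E"}

IOI_MS = 300            # inter-onset interval between successive sounds
SOUND_DURATION_MS = 220

#: ending-category proportions (TP level x location, exact by construction)
CATEGORY_PROPORTIONS = {
    "STANDARD": 0.72,
    "STAT_DEV": 0.08,
    "PHYS_DEV": 0.18,
    "DOUBLE_DEV": 0.02,
}
LOW_TP_PROPORTION = 0.10
ENDING_DEVIANT_LOCATION_PROPORTION = 0.20
ROOT_DEVIANT_LOCATION_PROPORTION = 0.05
#: minimum index gap between consecutive low-TP triplets (>= 3 intervening)
MIN_LOW_TP_GAP = 4

TARGET_ROLE = "TARGET"
TARGET_PITCH_HZ = 554.37  # C#5, higher-pitched cover-task target

#: marker codes used throughout the pipeline
EVENT_CODES = {
    "STANDARD": 1,
    "STAT_DEV": 2,
    "PHYS_DEV": 3,
    "DOUBLE_DEV": 4,
    "ROOT_1": 10,
    "ROOT_2": 11,
    "TARGET": 99,
}


class ParadigmError(ValueError):
    """Raised for infeasible or inconsistent paradigm configurations."""


class EndingCategory(str, enum.Enum):
    STANDARD = "STANDARD"
    STAT_DEV = "STAT_DEV"
    PHYS_DEV = "PHYS_DEV"
    DOUBLE_DEV = "DOUBLE_DEV"


def classify_ending(ending_tp: float, ending_location: str) -> EndingCategory:
    """Map (transition probability, location) to the four ending categories.

    Parameters
    ----------
    ending_tp : {0.9, 0.1}
    ending_location : {"standard", "deviant"}
    """
    if ending_tp not in (0.9, 0.1):
        raise ParadigmError(f"ending_tp must be 0.9 or 0.1, got {ending_tp!r}")
    if ending_location not in ("standard", "deviant"):
        raise ParadigmError(
            f"ending_location must be 'standard' or 'deviant', got {ending_location!r}"
        )
    if ending_tp == 0.9:
        return (
            EndingCategory.STANDARD
            if ending_location == "standard"
            else EndingCategory.PHYS_DEV
        )
    return (
        EndingCategory.STAT_DEV
        if ending_location == "standard"
        else EndingCategory.DOUBLE_DEV
    )


@dataclass(frozen=True)
class Triplet:
    """One root+ending unit with its deviance bookkeeping."""

    root: str                      # "AB" or "CD"
    ending: str                    # "E" or "F"
    ending_tp: float               # 0.9 or 0.1
    ending_location: str           # "standard" or "deviant"
    root_locations: tuple          # ("standard"/"deviant", ...) for both root sounds

    @property
    def category(self) -> EndingCategory:
        return classify_ending(self.ending_tp, self.ending_location)

    @property
    def is_low_tp(self) -> bool:
        return self.ending_tp == 0.1


@dataclass(frozen=True)
class StreamEvent:
    """A single sound presentation in the continuous stream."""

    block: int
    triplet_index: int     # -1 for targets inserted between triplets
    position: int          # 1..3 within the triplet; 0 for targets
    role: str              # "A".."F" or "TARGET"
    onset_ms: int
    location: str          # "left" or "right"
    is_target: bool = False


@dataclass
class ExperimentDesign:
    """Per-participant experiment configuration.

    ``role_permutation`` maps abstract roles A..F to concrete sound indices
    0..5 so that acoustical idiosyncrasies of individual sounds cannot bias
    role-linked effects across participants.
    """

    participant_id: int
    master_seed: int
    role_permutation: dict
    n_blocks: int = 6
    triplets_per_block: int = 400
    standard_side_per_block: list = field(default_factory=list)
    target_rate: int = 10  # cover-task targets inserted per block

    def __post_init__(self):
        perm = self.role_permutation
        if sorted(perm.keys()) != sorted(ROLES) or sorted(perm.values()) != list(
            range(6)
        ):
            raise ParadigmError("role_permutation must be a bijection A..F -> 0..5")
        if len(self.standard_side_per_block) != self.n_blocks:
            raise ParadigmError("standard_side_per_block must have length n_blocks")
        _check_divisibility(self.triplets_per_block)

    def child_seed(self, *keys: int) -> np.random.SeedSequence:
        """Derive a reproducible child seed for a (purpose, block, ...) key."""
        return np.random.SeedSequence(
            [int(self.master_seed), int(self.participant_id), *map(int, keys)]
        )

    def rng(self, *keys: int) -> np.random.Generator:
        return np.random.default_rng(self.child_seed(*keys))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        d = json.loads(text)
        d["role_permutation"] = {k: int(v) for k, v in d["role_permutation"].items()}
        return cls(**d)


@dataclass
class TripletSequence:
    """One block's ordered triplets and their flattened sound events."""

    design: ExperimentDesign
    block_index: int
    triplets: list          # list[Triplet]
    events: list            # list[StreamEvent]

    @property
    def standard_side(self) -> str:
        return self.design.standard_side_per_block[self.block_index]

    def category_counts(self) -> dict:
        counts = {c.value: 0 for c in EndingCategory}
        for t in self.triplets:
            counts[t.category.value] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """One row per StreamEvent (the events-TSV external interface)."""
        rows = []
        for ev in self.events:
            if ev.is_target:
                tp, cat, sound = "", "TARGET", "target"
            else:
                trip = self.triplets[ev.triplet_index]
                if ev.position == 3:
                    tp, cat = trip.ending_tp, trip.category.value
                else:
                    tp, cat = "", f"ROOT_{ev.position}"
                sound = str(self.design.role_permutation[ev.role])
            rows.append(
                dict(
                    onset_ms=ev.onset_ms,
                    block=ev.block,
                    triplet_index=ev.triplet_index,
                    position=ev.position,
                    role=ev.role,
                    concrete_sound=sound,
                    location=ev.location,
                    ending_tp=tp,
                    category=cat,
                    is_target=ev.is_target,
                )
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FamiliarityTrial:
    """Two-alternative forced-choice trial of the post-block familiarity test."""

    first_sequence: Triplet
    second_sequence: Triplet
    correct_choice: int        # 1 or 2: which sequence has the high-TP ending
    pause_ms: int = 335


def _check_divisibility(n: int) -> None:
    for name, p in CATEGORY_PROPORTIONS.items():
        if abs(n * p - round(n * p)) > 1e-9:
            raise ParadigmError(
                f"triplets_per_block={n}: {name} count {n}*{p} is not an integer"
            )
    for label, p in (
        ("low-TP per root", LOW_TP_PROPORTION / 2),
        ("root location deviants", 2 * ROOT_DEVIANT_LOCATION_PROPORTION),
    ):
        if abs(n * p - round(n * p)) > 1e-9:
            raise ParadigmError(f"triplets_per_block={n}: {label} is not an integer")


def make_design(
    participant_id: int,
    master_seed: int,
    n_blocks: int = 6,
    triplets_per_block: int = 400,
    target_rate: int = 10,
) -> ExperimentDesign:
    """Build a participant's design: role permutation and side counterbalancing.

    Deterministic in ``(participant_id, master_seed)``.  Standard sides
    alternate block-by-block so each side is standard in half the blocks;
    which side starts is counterbalanced by participant parity.
    """
    if n_blocks % 2:
        raise ParadigmError("n_blocks must be even to counterbalance sides")
    _check_divisibility(triplets_per_block)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(participant_id), 0])
    )
    perm = {role: int(i) for role, i in zip(ROLES, rng.permutation(6))}
    first = "left" if participant_id % 2 == 0 else "right"
    other = "right" if first == "left" else "left"
    sides = [first if b % 2 == 0 else other for b in range(n_blocks)]
    return ExperimentDesign(
        participant_id=participant_id,
        master_seed=master_seed,
        role_permutation=perm,
        n_blocks=n_blocks,
        triplets_per_block=triplets_per_block,
        standard_side_per_block=sides,
        target_rate=target_rate,
    )


def _sample_gapped_positions(
    n: int, k: int, min_gap: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly sample k sorted positions in range(n) with consecutive
    differences >= min_gap (classic stars-and-bars bijection)."""
    slack = n - (k - 1) * (min_gap - 1)
    if slack < k:
        raise ParadigmError(
            f"cannot place {k} low-TP triplets with gap {min_gap} in {n}"
        )
    base = np.sort(rng.choice(slack, size=k, replace=False))
    return base + np.arange(k) * (min_gap - 1)


def _assign_roots(
    n: int, low_positions: set, rng: np.random.Generator, max_attempts: int = 10_000
) -> list:
    """Assign a root to every triplet position under exact-count constraints.

    Counts: n/2 of each root; low-TP endings split equally across roots.  The
    following root is chosen to keep, for each ending letter, the counts of
    subsequent AB/CD balanced (empirical ending->root TP = 0.5 within
    rounding), subject to remaining supply; bounded rejection-resampling.
    """
    n_low_per_root = int(round(n * LOW_TP_PROPORTION / 2))
    n_high_per_root = n // 2 - n_low_per_root
    for _ in range(max_attempts):
        supply = {
            ("AB", True): n_low_per_root,
            ("AB", False): n_high_per_root,
            ("CD", True): n_low_per_root,
            ("CD", False): n_high_per_root,
        }
        # ending letter -> counts of the root that followed it
        follow = {"E": {"AB": 0, "CD": 0}, "F": {"AB": 0, "CD": 0}}
        roots: list = []
        prev_ending = None
        ok = True
        for i in range(n):
            low = i in low_positions
            cands = [r for r in ROOTS if supply[(r, low)] > 0]
            if not cands:
                ok = False
                break
            if len(cands) == 1 or prev_ending is None:
                choice = cands[rng.integers(len(cands))]
            else:
                c = follow[prev_ending]
                if c["AB"] < c["CD"] and "AB" in cands:
                    choice = "AB"
                elif c["CD"] < c["AB"] and "CD" in cands:
                    choice = "CD"
                else:
                    choice = cands[rng.integers(len(cands))]
            supply[(choice, low)] -= 1
            ending = LOW_ENDING[choice] if low else HIGH_ENDING[choice]
            if prev_ending is not None:
                follow[prev_ending][choice] += 1
            prev_ending = ending
            roots.append(choice)
        if ok:
            return roots
    raise ParadigmError("root assignment failed after bounded retries")


def generate_block(
    design: ExperimentDesign, block_index: int, seed=None
) -> TripletSequence:
    """Generate one block's pseudorandom triplet stream.

    Postconditions at the default 400 triplets: category counts exactly
    {288, 32, 72, 8}; low-TP triplets split 20/20 across roots and separated
    by >= 3 other triplets; exactly 5 % of root sounds on the deviant side;
    300 ms IOI throughout.  Deterministic for a given (design, block, seed).
    """
    if not 0 <= block_index < design.n_blocks:
        raise ParadigmError(f"block_index {block_index} out of range")
    n = design.triplets_per_block
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else design.rng(1, block_index)
    )

    n_low = int(round(n * LOW_TP_PROPORTION))
    low_pos = set(_sample_gapped_positions(n, n_low, MIN_LOW_TP_GAP, rng).tolist())
    roots = _assign_roots(n, low_pos, rng)

    # exact-count location deviance: endings (Table 2 product structure) ...
    low_idx = np.array(sorted(low_pos))
    high_idx = np.array(sorted(set(range(n)) - low_pos))
    n_double = int(round(n * CATEGORY_PROPORTIONS["DOUBLE_DEV"]))
    n_phys = int(round(n * CATEGORY_PROPORTIONS["PHYS_DEV"]))
    deviant_endings = set(rng.choice(low_idx, size=n_double, replace=False).tolist())
    deviant_endings |= set(rng.choice(high_idx, size=n_phys, replace=False).tolist())
    # ... and root sounds (5 % of the 2n root-sound presentations)
    n_root_dev = int(round(2 * n * ROOT_DEVIANT_LOCATION_PROPORTION))
    root_dev_flat = set(rng.choice(2 * n, size=n_root_dev, replace=False).tolist())

    triplets = []
    for i, root in enumerate(roots):
        low = i in low_pos
        triplets.append(
            Triplet(
                root=root,
                ending=LOW_ENDING[root] if low else HIGH_ENDING[root],
                ending_tp=0.1 if low else 0.9,
                ending_location="deviant" if i in deviant_endings else "standard",
                root_locations=tuple(
                    "deviant" if 2 * i + j in root_dev_flat else "standard"
                    for j in range(2)
                ),
            )
        )

    std_side = design.standard_side_per_block[block_index]
    dev_side = "right" if std_side == "left" else "left"
    events = []
    for i, trip in enumerate(triplets):
        for pos in (1, 2, 3):
            if pos == 3:
                loc = trip.ending_location
                role = trip.ending
            else:
                loc = trip.root_locations[pos - 1]
                role = trip.root[pos - 1]
            events.append(
                StreamEvent(
                    block=block_index,
                    triplet_index=i,
                    position=pos,
                    role=role,
                    onset_ms=(3 * i + pos - 1) * IOI_MS,
                    location=std_side if loc == "standard" else dev_side,
                )
            )
    return TripletSequence(
        design=design, block_index=block_index, triplets=triplets, events=events
    )


def insert_targets(
    sequence: TripletSequence, design: ExperimentDesign, seed=None
) -> TripletSequence:
    """Insert cover-task target sounds between triplets.

    Targets occupy one 300 ms slot at a triplet boundary (shifting later
    events), and are never placed within three triplets of a low-TP triplet
    so that deviant epochs stay clear of the post-target exclusion window.
    """
    rate = design.target_rate
    if rate == 0:
        return sequence
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else design.rng(2, sequence.block_index)
    )
    n = len(sequence.triplets)
    low = {i for i, t in enumerate(sequence.triplets) if t.is_low_tp}
    legal = [
        b
        for b in range(1, n)  # a target before triplet b
        if not any(j in low for j in range(b - 3, b + 3))
    ]
    if rate > len(legal):
        raise ParadigmError(f"cannot place {rate} targets; {len(legal)} legal slots")
    chosen = sorted(rng.choice(len(legal), size=rate, replace=False).tolist())
    boundaries = [legal[c] for c in chosen]

    std_side = sequence.standard_side
    events = []
    shift = 0
    bi = 0
    for ev in sequence.events:
        while bi < len(boundaries) and ev.position == 1 and ev.triplet_index == boundaries[bi]:
            events.append(
                StreamEvent(
                    block=sequence.block_index,
                    triplet_index=-1,
                    position=0,
                    role=TARGET_ROLE,
                    onset_ms=ev.onset_ms + shift,
                    location=std_side,
                    is_target=True,
                )
            )
            shift += IOI_MS
            bi += 1
        events.append(dataclasses.replace(ev, onset_ms=ev.onset_ms + shift))
    return TripletSequence(
        design=sequence.design,
        block_index=sequence.block_index,
        triplets=sequence.triplets,
        events=events,
    )


@dataclass
class TransitionMatrix:
    """Empirical conditional probabilities of the generated stream."""

    root_to_ending: pd.DataFrame   # P(ending | root), rows sum to 1
    ending_to_root: pd.DataFrame   # P(next root | ending), rows sum to 1


def transition_matrix(sequence: TripletSequence) -> TransitionMatrix:
    """Counts-based maximum-likelihood transition estimates for one block."""
    trips = sequence.triplets
    if not trips:
        raise ParadigmError("empty sequence")
    r2e = pd.DataFrame(0.0, index=list(ROOTS), columns=list(ENDINGS))
    for t in trips:
        r2e.loc[t.root, t.ending] += 1
    e2r = pd.DataFrame(0.0, index=list(ENDINGS), columns=list(ROOTS))
    for prev, nxt in zip(trips[:-1], trips[1:]):
        e2r.loc[prev.ending, nxt.root] += 1
    r2e = r2e.div(r2e.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    e2r = e2r.div(e2r.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    return TransitionMatrix(root_to_ending=r2e, ending_to_root=e2r)


def validate_sequence(sequence: TripletSequence) -> list:
    """Check every generator invariant; return a list of violation messages."""
    violations = []
    n = len(sequence.triplets)
    expected = {
        name: int(round(n * p)) for name, p in CATEGORY_PROPORTIONS.items()
    }
    counts = sequence.category_counts()
    if counts != expected:
        violations.append(f"category counts {counts} != expected {expected}")

    low_idx = [i for i, t in enumerate(sequence.triplets) if t.is_low_tp]
    for a, b in zip(low_idx[:-1], low_idx[1:]):
        if b - a < MIN_LOW_TP_GAP:
            violations.append(f"low-TP triplets at {a} and {b}: gap {b - a} < {MIN_LOW_TP_GAP}")
    per_root_low = {r: sum(1 for i in low_idx if sequence.triplets[i].root == r) for r in ROOTS}
    if len(set(per_root_low.values())) != 1:
        violations.append(f"low-TP endings unbalanced across roots: {per_root_low}")

    n_root_sounds = 2 * n
    n_dev = sum(
        loc == "deviant" for t in sequence.triplets for loc in t.root_locations
    )
    want = int(round(n_root_sounds * ROOT_DEVIANT_LOCATION_PROPORTION))
    if n_dev != want:
        violations.append(f"root-sound deviant locations {n_dev} != {want}")

    onsets = [ev.onset_ms for ev in sequence.events]
    if any(b - a != IOI_MS for a, b in zip(onsets[:-1], onsets[1:])):
        violations.append("inter-onset spacing != 300 ms somewhere")
    if any(b <= a for a, b in zip(onsets[:-1], onsets[1:])):
        violations.append("onsets not strictly increasing")

    for r in ROOTS:
        trips_r = [t for t in sequence.triplets if t.root == r]
        hi = sum(1 for t in trips_r if not t.is_low_tp)
        if trips_r and abs(hi / len(trips_r) - 0.9) > 1e-9:
            violations.append(f"P(high ending | {r}) = {hi / len(trips_r):.4f} != 0.9")
    return violations


def make_familiarity_test(
    design: ExperimentDesign, block_index: int, seed=None
) -> list:
    """Build the 12-trial two-alternative familiarity test for one block.

    Each of the four ordered pairings (ABE/ABF, ABF/ABE, CDF/CDE, CDE/CDF)
    appears three times; consecutive trials never share a root (with 6 + 6
    trials per root this forces strict alternation); exactly one sequence per
    trial carries the high-TP ending.
    """
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else design.rng(3, block_index)
    )

    def triplet(root, ending):
        return Triplet(
            root=root,
            ending=ending,
            ending_tp=0.9 if HIGH_ENDING[root] == ending else 0.1,
            ending_location="standard",
            root_locations=("standard", "standard"),
        )

    per_root = {}
    for root in ROOTS:
        hi, lo = HIGH_ENDING[root], LOW_ENDING[root]
        orders = [ (hi, lo) ] * 3 + [ (lo, hi) ] * 3
        rng.shuffle(orders)
        per_root[root] = orders
    first_root = ROOTS[rng.integers(2)]
    trials = []
    for i in range(12):
        root = first_root if i % 2 == 0 else ({"AB": "CD", "CD": "AB"}[first_root])
        e1, e2 = per_root[root][i // 2]
        trials.append(
            FamiliarityTrial(
                first_sequence=triplet(root, e1),
                second_sequence=triplet(root, e2),
                correct_choice=1 if HIGH_ENDING[root] == e1 else 2,
            )
        )
    return trials
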