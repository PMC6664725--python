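"""Train/validation/test assignment of drug-cell interaction pairs.

Four protocols are provided:

* ``pair``        — measured pairs shuffled and partitioned by fractions
                    (default 80/10/10); drugs and cell lines may recur
                    across partitions, only pairs are disjoint.
* ``drug_blind``  — whole drugs held out: every pair of the sampled test
                    drugs goes to test, remaining pairs split 90/10 into
                    train/validation.  Measures generalization to novel
                    compounds.
* ``cell_blind``  — the same with cell lines held out.
* ``tissue_blind``— every pair of one tissue type held out; the rest mixed
                    and split 90/10.

``subsample_training`` shrinks the training partition for learning curves;
subsets at nested fractions under one seed are themselves nested, which
removes sampling variance between adjacent curve points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .gdsc_io import InteractionTable

__all__ = [
    "SplitError",
    "SplitSpec",
    "pair_split",
    "entity_blind_split",
    "tissue_blind_split",
    "subsample_training",
    "validate_split",
    "PAPER_PRESETS",
]

Pair = tuple[str, str]

#: Held-out entity counts as printed for the full 223-drug / 948-cell panel.
PAPER_PRESETS = {"drug_blind": 23, "cell_blind": 94}


class SplitError(ValueError):
    """A split request or a SplitSpec violates its protocol contract."""


@dataclass(frozen=True)
class SplitSpec:
    train_pairs: tuple[Pair, ...]
    val_pairs: tuple[Pair, ...]
    test_pairs: tuple[Pair, ...]
    protocol: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "protocol": self.protocol,
            "seed": self.seed,
            "params": self.params,
            "train_pairs": [list(p) for p in self.train_pairs],
            "val_pairs": [list(p) for p in self.val_pairs],
            "test_pairs": [list(p) for p in self.test_pairs],
        })

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        d = json.loads(text)
        return cls(
            train_pairs=tuple(tuple(p) for p in d["train_pairs"]),
            val_pairs=tuple(tuple(p) for p in d["val_pairs"]),
            test_pairs=tuple(tuple(p) for p in d["test_pairs"]),
            protocol=d["protocol"], seed=d["seed"], params=d["params"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _shuffled_pairs(pairs: list[Pair], rng: np.random.Generator) -> list[Pair]:
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def pair_split(
    table: InteractionTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitSpec:
    """Partition measured pairs into train/val/test by shuffled fractions.

    Validation and test sizes are floored; the remainder goes to training.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError(f"fractions {fractions} do not sum to 1")
    pairs = _shuffled_pairs(table.known_pairs(), np.random.default_rng(seed))
    n = len(pairs)
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise SplitError(f"{n} pairs cannot fill all three partitions "
                         f"at fractions {fractions}")
    return SplitSpec(
        train_pairs=tuple(pairs[:n_train]),
        val_pairs=tuple(pairs[n_train:n_train + n_val]),
        test_pairs=tuple(pairs[n_train + n_val:]),
        protocol="pair", seed=seed, params={"fractions": list(fractions)},
    )


def entity_blind_split(
    table: InteractionTable,
    entity: str,
    n_test_entities: int | None = None,
    test_fraction: float = 0.1,
    inner_val_fraction: float = 0.1,
    seed: int = 0,
) -> SplitSpec:
    """Hold out whole drugs or cell lines for the blind-test protocol.

    ``n_test_entities`` entities (drugs if ``entity == "drug"``, else cell
    lines) are sampled; all their measured pairs form the test set and none
    of them appears in train or validation.  When ``n_test_entities`` is not
    given it is ``round(test_fraction * n_entities)``.  The remaining pairs
    are split ``1 - inner_val_fraction`` / ``inner_val_fraction`` into
    train/validation at the pair level.
    """
    if entity not in ("drug", "cell"):
        raise SplitError(f"unknown entity kind {entity!r}")
    ids = table.drug_ids if entity == "drug" else table.cell_ids
    if n_test_entities is None:
        n_test_entities = round(test_fraction * len(ids))
    if not 1 <= n_test_entities < len(ids):
        raise SplitError(
            f"cannot hold out {n_test_entities} of {len(ids)} {entity}s")
    rng = np.random.default_rng(seed)
    held = set(rng.choice(np.array(ids, dtype=object), size=n_test_entities,
                          replace=False).tolist())
    key = 0 if entity == "drug" else 1
    test = [p for p in table.known_pairs() if p[key] in held]
    rest = _shuffled_pairs(
        [p for p in table.known_pairs() if p[key] not in held], rng)
    n_val = int(len(rest) * inner_val_fraction)
    if n_val < 1 or len(rest) - n_val < 1:
        raise SplitError("too few remaining pairs for train/validation")
    return SplitSpec(
        train_pairs=tuple(rest[n_val:]),
        val_pairs=tuple(rest[:n_val]),
        test_pairs=tuple(test),
        protocol=f"{entity}_blind", seed=seed,
        params={"n_test_entities": int(n_test_entities),
                "held_out": sorted(held),
                "inner_val_fraction": inner_val_fraction},
    )


def tissue_blind_split(
    table: InteractionTable,
    held_out_tissue: str,
    inner_val_fraction: float = 0.1,
    seed: int = 0,
) -> SplitSpec:
    """Hold out every pair of one tissue type; mix and split the rest 90/10."""
    tissue_of = {c.cell_id: c.tissue for c in table.cells}
    if held_out_tissue not in set(tissue_of.values()):
        raise SplitError(f"tissue {held_out_tissue!r} not present in the table")
    test = [p for p in table.known_pairs() if tissue_of[p[1]] == held_out_tissue]
    rng = np.random.default_rng(seed)
    rest = _shuffled_pairs(
        [p for p in table.known_pairs() if tissue_of[p[1]] != held_out_tissue],
        rng)
    n_val = int(len(rest) * inner_val_fraction)
    if not test or n_val < 1 or len(rest) - n_val < 1:
        raise SplitError("partition would be empty under this tissue hold-out")
    return SplitSpec(
        train_pairs=tuple(rest[n_val:]),
        val_pairs=tuple(rest[:n_val]),
        test_pairs=tuple(test),
        protocol="tissue_blind", seed=seed,
        params={"held_out_tissue": held_out_tissue,
                "inner_val_fraction": inner_val_fraction},
    )


def subsample_training(split: SplitSpec, fraction: float, seed: int = 0) -> SplitSpec:
    """Reduce the training partition to ``round(fraction * n)`` pairs.

    A single seeded ordering of the training pairs is used and the first
    k taken, so subsets at fractions f1 < f2 under the same seed are nested.
    Validation and test partitions are untouched.
    """
    if not 0.0 < fraction <= 1.0:
        raise SplitError(f"fraction {fraction} outside (0, 1]")
    if fraction == 1.0:
        return split
    rng = np.random.default_rng(seed)
    ordered = _shuffled_pairs(list(split.train_pairs), rng)
    k = round(fraction * len(ordered))
    if k < 1:
        raise SplitError(f"fraction {fraction} leaves an empty training set")
    return replace(
        split,
        train_pairs=tuple(ordered[:k]),
        params={**split.params, "train_fraction": fraction,
                "subsample_seed": seed},
    )


def validate_split(table: InteractionTable, split: SplitSpec) -> None:
    """Assert SplitSpec invariants; raise :class:`SplitError` on any leak.

    Checks pairwise disjointness, membership in the measured set, and for
    the blind protocols the entity-level disjointness between the test
    partition and train/validation.
    """
    parts = {"train": set(split.train_pairs), "val": set(split.val_pairs),
             "test": set(split.test_pairs)}
    names = list(parts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = parts[a] & parts[b]
            if overlap:
                raise SplitError(f"{a}/{b} share {len(overlap)} pair(s)")
    known = set(table.known_pairs())
    for name, pairs in parts.items():
        stray = pairs - known
        if stray:
            raise SplitError(f"{name} contains {len(stray)} unmeasured pair(s)")

    if split.protocol in ("drug_blind", "cell_blind"):
        key = 0 if split.protocol == "drug_blind" else 1
        test_entities = {p[key] for p in parts["test"]}
        seen = {p[key] for p in parts["train"] | parts["val"]}
        leak = test_entities & seen
        if leak:
            raise SplitError(
                f"{split.protocol}: entities {sorted(leak)[:3]} leak into training")
    elif split.protocol == "tissue_blind":
        tissue_of = {c.cell_id: c.tissue for c in table.cells}
        held = split.params.get("held_out_tissue")
        for name in ("train", "val"):
            if any(tissue_of[c] == held for _, c in parts[name]):
                raise SplitError(f"tissue {held!r} leaks into {name}")
        if any(tissue_of[c] != held for _, c in parts["test"]):
            raise SplitError("test contains a cell outside the held-out tissue")
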