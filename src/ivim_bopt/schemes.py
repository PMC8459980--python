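"""b-value acquisition schemes and the candidate-set ensemble.

The acquired palette is the 16-b-value brain protocol (0-900 s/mm^2); every
ensemble-generated subset keeps the fixed base {0, 200, 900} s/mm^2 (200 and
900 being the literature-suggested anchors for estimating the perfusion
fraction).  Three deterministic selection strategies grow subsets from that
base: "low" adds sub-200 values in ascending b (dense sampling of the
perfusion regime), "high" adds values above 200 (stabilizing the diffusion
tail), "alternating" interleaves one low and one high addition (mid-range
emphasis).  Manually supplied sets may augment the pool.

Scan-time accounting: a b=0 measurement costs one TR, a diffusion-weighted
measurement costs one TR per diffusion direction (default 3).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "PALETTE",
    "BASE_BVALUES",
    "BValueScheme",
    "EnsembleSpec",
    "generate_strategy_sets",
    "build_ensemble",
    "scan_time",
    "load_schemes_yaml",
    "save_schemes_yaml",
    "load_suggested_schemes",
]

#: The acquired 16-b-value palette (s/mm^2).
PALETTE = (0, 10, 20, 40, 80, 110, 140, 170, 200, 300, 400, 500, 600, 700, 800, 900)

#: b values fixed in every ensemble-generated subset.
BASE_BVALUES = (0, 200, 900)

STRATEGIES = ("low", "high", "alternating", "manual")


@dataclass(frozen=True)
class BValueScheme:
    """Ordered b values with a number of averages per b value."""

    bvalues: tuple
    averages: tuple = None
    label: str = ""
    strategy: str = "manual"
    tr: float = 4.0  # s
    directions: int = 3

    def __post_init__(self):
        b = tuple(float(x) for x in self.bvalues)
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"b values must be strictly increasing, got {b}")
        if any(x < 0 for x in b):
            raise ValueError("b values must be non-negative")
        avg = self.averages
        avg = tuple(int(a) for a in (avg if avg is not None else [1] * len(b)))
        if len(avg) != len(b):
            raise ValueError("averages must have one entry per b value")
        if any(a < 1 for a in avg):
            raise ValueError("averages must be >= 1")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "averages", avg)

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def n_measurements(self) -> int:
        return sum(self.averages)

    def contains_base(self, base=BASE_BVALUES) -> bool:
        return set(float(b) for b in base) <= set(self.bvalues)

    def with_averages(self, averages) -> "BValueScheme":
        if isinstance(averages, int):
            averages = [averages] * len(self)
        return replace(self, averages=tuple(int(a) for a in averages))

    def to_string(self) -> str:
        """Human-readable "b (N)" notation, e.g. "0 (5), 200 (5), 900 (5)"."""
        return ", ".join(
            f"{int(b) if float(b).is_integer() else b} ({n})"
            for b, n in zip(self.bvalues, self.averages)
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "strategy": self.strategy,
            "bvalues": [float(b) for b in self.bvalues],
            "averages": list(self.averages),
        }


def scan_time(scheme: BValueScheme, tr: float | None = None,
              directions: int | None = None) -> float:
    """Scan time in seconds: b=0 costs 1 TR, weighted b cost `directions` TRs."""
    tr = scheme.tr if tr is None else tr
    directions = scheme.directions if directions is None else directions
    if tr <= 0:
        raise ValueError("tr must be positive")
    return float(
        sum(
            n * tr * (1 if b == 0 else directions)
            for b, n in zip(scheme.bvalues, scheme.averages)
        )
    )


def generate_strategy_sets(palette=PALETTE, strategy="low",
                           base=BASE_BVALUES) -> list[BValueScheme]:
    """Nested growing subsets from the fixed base, one scheme per increment.

    The zeroth element is the base itself; additions follow ascending b within
    each pool (values below 200 for "low", values above 200 excluding the base
    anchor 900 for "high"); "alternating" interleaves, starting low.
    """
    palette = tuple(sorted(float(b) for b in set(palette)))
    base_set = set(float(b) for b in base)
    if not base_set <= set(palette):
        raise ValueError(f"palette must contain the base {base}")
    lows = [b for b in palette if 0 < b < 200 and b not in base_set]
    highs = [b for b in palette if b > 200 and b not in base_set]
    if strategy == "low":
        additions = lows
    elif strategy == "high":
        additions = highs
    elif strategy == "alternating":
        additions = []
        for i in range(max(len(lows), len(highs))):
            if i < len(lows):
                additions.append(lows[i])
            if i < len(highs):
                additions.append(highs[i])
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected low/high/alternating")

    sets = []
    current = sorted(base_set)
    sets.append(_strategy_scheme(current, strategy, 0))
    for i, b in enumerate(additions, start=1):
        current = sorted(current + [b])
        sets.append(_strategy_scheme(current, strategy, i))
    return sets


def _strategy_scheme(bvalues, strategy, i) -> BValueScheme:
    return BValueScheme(
        bvalues=tuple(bvalues),
        label=f"{strategy}-{len(bvalues)}b" if i or strategy != "manual" else "base",
        strategy=strategy if i else "base",
    )


@dataclass(frozen=True)
class EnsembleSpec:
    """De-duplicated, deterministically ordered pool of candidate schemes."""

    schemes: tuple

    def __len__(self) -> int:
        return len(self.schemes)

    def __iter__(self):
        return iter(self.schemes)

    def labels(self) -> list[str]:
        return [s.label for s in self.schemes]


def build_ensemble(palette=PALETTE, manual_sets=(), base=BASE_BVALUES) -> EnsembleSpec:
    """Union of the three strategy sequences plus manual sets.

    De-duplicated on the b-value tuple and ordered by (size, b list); manual
    sets missing the fixed base are rejected.
    """
    pool: dict[tuple, BValueScheme] = {}
    for strategy in ("low", "high", "alternating"):
        for s in generate_strategy_sets(palette, strategy, base):
            pool.setdefault(s.bvalues, s)
    for s in manual_sets:
        if not s.contains_base(base):
            raise ValueError(
                f"manual scheme {s.label or s.bvalues} lacks the fixed base {base}"
            )
        pool.setdefault(s.bvalues, replace(s, strategy="manual"))
    ordered = sorted(pool.values(), key=lambda s: (len(s), s.bvalues))
    return EnsembleSpec(schemes=tuple(ordered))


def save_schemes_yaml(schemes, path) -> None:
    payload = [s.to_dict() for s in schemes]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_schemes_yaml(path) -> list[BValueScheme]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [_scheme_from_dict(d) for d in payload]


def _scheme_from_dict(d: dict) -> BValueScheme:
    return BValueScheme(
        bvalues=tuple(d["bvalues"]),
        averages=tuple(d["averages"]) if d.get("averages") else None,
        label=d.get("label", ""),
        strategy=d.get("strategy", "manual"),
    )


def load_suggested_schemes() -> list[BValueScheme]:
    """Published suggested optimized brain-IVIM schemes (3/6/12-minute budgets)."""
    ref = importlib.resources.files("ivim_bopt.data") / "suggested_schemes.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_schemes_yaml(path)
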