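"""Epigenetic-clock site registries.

Epigenetic clocks are weighted linear combinations of DNA-methylation beta
values at selected CpG sites.  First-generation clocks (Horvath, Hannum,
Weidner, Zhang elastic-net) are trained to predict chronological age;
second/third-generation clocks (PhenoAge, DNAmTL, DunedinPACE) to predict
age-related phenotypes, mortality, or pace of ageing.  This module loads
per-clock coefficient tables, orients the telomere-length clock (whose
coefficients have the opposite meaning, since telomeres shorten with age),
and partitions the measured array universe into clock and non-clock sites
for the enrichment analyses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "Generation",
    "ClockDefinition",
    "SiteGroups",
    "load_clock",
    "load_bundled_clocks",
    "reverse_telomere_coefficients",
    "build_site_groups",
    "site_coefficient_direction",
    "make_mock_clock",
]


class Generation(str, Enum):
    """Clock training-target family."""

    FIRST = "first"
    SECOND_THIRD = "second_third"


@dataclass(frozen=True)
class ClockDefinition:
    """A named clock: its generation and (cpg_id, coefficient) pairs."""

    name: str
    generation: Generation
    sites: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.sites]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"clock {self.name!r}: duplicate cpg_id {dup!r}")
        for cpg, coef in self.sites:
            if not _finite(coef):
                raise ValueError(
                    f"clock {self.name!r}: non-finite coefficient for {cpg!r}"
                )

    @property
    def site_ids(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.sites)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class SiteGroups:
    """Partition of the array universe into clock groups and background.

    ``first_gen_sites`` / ``second_third_gen_sites`` are the deduplicated
    unions of the member clocks' site lists *before* intersecting with the
    universe; sites absent from the measured array are kept in the clock set
    but listed in ``off_array_sites`` and must be excluded from enrichment
    denominators (enrichment compares within the measured array only).
    """

    first_gen_sites: frozenset[str]
    second_third_gen_sites: frozenset[str]
    array_universe: frozenset[str]
    off_array_sites: frozenset[str] = field(default_factory=frozenset)

    def on_array(self, group: Generation | str) -> frozenset[str]:
        """Clock sites of ``group`` restricted to the measured universe."""
        return self.group_sites(group) & self.array_universe

    def group_sites(self, group: Generation | str) -> frozenset[str]:
        g = Generation(group)
        if g is Generation.FIRST:
            return self.first_gen_sites
        return self.second_third_gen_sites

    def background(self, group: Generation | str) -> frozenset[str]:
        """Non-clock background for one comparison: universe minus that group."""
        return self.array_universe - self.group_sites(group)

    def to_frame(self, clocks: Iterable[ClockDefinition] = ()):
        """One row per clock site with group and per-clock membership columns."""
        import pandas as pd

        clocks = list(clocks)
        sites = sorted(self.first_gen_sites | self.second_third_gen_sites)
        rows = []
        for s in sites:
            row = {
                "cpg_id": s,
                "first_gen": s in self.first_gen_sites,
                "second_third_gen": s in self.second_third_gen_sites,
                "on_array": s in self.array_universe,
            }
            for c in clocks:
                row[c.name] = s in c.site_ids
            rows.append(row)
        return pd.DataFrame(rows)


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def load_clock(path: str | Path, name: str, generation: Generation | str) -> ClockDefinition:
    """Read a clock coefficient CSV (columns ``cpg_id,coefficient``).

    Coefficient signs are preserved exactly as stored.
    """
    path = Path(path)
    sites: list[tuple[str, float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"cpg_id", "coefficient"} <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected header with columns cpg_id, coefficient"
            )
        for lineno, row in enumerate(reader, start=2):
            cpg = row["cpg_id"].strip()
            raw = row["coefficient"].strip()
            try:
                coef = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric coefficient {raw!r} on line {lineno}"
                ) from None
            sites.append((cpg, coef))
    if not sites:
        raise ValueError(f"{path}: clock file is empty")
    return ClockDefinition(name=name, generation=Generation(generation), sites=tuple(sites))


#: Bundled synthetic clock fixtures: (file stem, display name, generation).
#: Site counts mirror the published clocks (Horvath 353, Hannum 71,
#: Weidner 102, Zhang elastic-net 514; PhenoAge 513, DNAmTL 140,
#: DunedinPACE 173) but cpg ids and coefficients are synthetic stand-ins.
BUNDLED_CLOCKS: tuple[tuple[str, str, Generation], ...] = (
    ("horvath_synthetic", "Horvath", Generation.FIRST),
    ("hannum_synthetic", "Hannum", Generation.FIRST),
    ("weidner_synthetic", "Weidner", Generation.FIRST),
    ("zhang_en_synthetic", "ZhangEN", Generation.FIRST),
    ("phenoage_synthetic", "PhenoAge", Generation.SECOND_THIRD),
    ("dnamtl_synthetic", "DNAmTL", Generation.SECOND_THIRD),
    ("dunedinpace_synthetic", "DunedinPACE", Generation.SECOND_THIRD),
)


def load_bundled_clocks(reverse_dnamtl: bool = True) -> list[ClockDefinition]:
    """Load the seven synthetic clock fixtures shipped with the package.

    With ``reverse_dnamtl`` the telomere-length clock's coefficients are
    negated so that a positive coefficient means "contributes positively to
    the age(ing) estimate" consistently across clocks.
    """
    clocks = []
    base = resources.files("clocktraj") / "data" / "synthetic_clocks"
    for stem, name, gen in BUNDLED_CLOCKS:
        with resources.as_file(base / f"{stem}.csv") as p:
            clock = load_clock(p, name, gen)
        if reverse_dnamtl and name == "DNAmTL":
            clock = reverse_telomere_coefficients(clock)
        clocks.append(clock)
    return clocks


def reverse_telomere_coefficients(clock: ClockDefinition) -> ClockDefinition:
    """Negate every coefficient (telomere length shortens with age)."""
    return replace(clock, sites=tuple((c, -v) for c, v in clock.sites))


def build_site_groups(
    clocks: Iterable[ClockDefinition], universe: Iterable[str]
) -> SiteGroups:
    """Union per-generation clock site lists and situate them in a universe.

    The unions deduplicate sites shared between clocks.  Sites missing from
    the universe are retained in the groups but flagged in
    ``off_array_sites``.
    """
    clocks = list(clocks)
    if not clocks:
        raise ValueError("build_site_groups: empty clock list")
    uni = frozenset(universe)
    if not uni:
        raise ValueError("build_site_groups: empty universe")
    first: set[str] = set()
    second: set[str] = set()
    for c in clocks:
        (first if c.generation is Generation.FIRST else second).update(c.site_ids)
    off = (first | second) - uni
    return SiteGroups(
        first_gen_sites=frozenset(first),
        second_third_gen_sites=frozenset(second),
        array_universe=uni,
        off_array_sites=frozenset(off),
    )


def site_coefficient_direction(
    clocks: Iterable[ClockDefinition], sites: Iterable[str] | None = None
) -> dict[str, str]:
    """Label each site's coefficient direction across the clocks containing it.

    Returns ``{cpg_id: "positive" | "negative" | "mixed"}``.  Apply
    :func:`reverse_telomere_coefficients` to DNAmTL first so directions are
    comparable across clocks.  Zero coefficients are treated as sign-less and
    ignored unless a site has only zeros, which labels it ``mixed``.
    """
    signs: dict[str, set[int]] = {}
    for clock in clocks:
        for cpg, coef in clock.sites:
            signs.setdefault(cpg, set()).add(0 if coef == 0 else (1 if coef > 0 else -1))
    wanted = signs.keys() if sites is None else list(sites)
    out: dict[str, str] = {}
    for cpg in wanted:
        if cpg not in signs:
            raise KeyError(f"site {cpg!r} appears in no clock")
        s = signs[cpg] - {0}
        if s == {1}:
            out[cpg] = "positive"
        elif s == {-1}:
            out[cpg] = "negative"
        else:
            out[cpg] = "mixed"
    return out


def make_mock_clock(
    name: str,
    site_ids: Iterable[str],
    generation: Generation | str = Generation.FIRST,
    coefficients: Iterable[float] | None = None,
    seed: int | None = 0,
) -> ClockDefinition:
    """Build a clock from explicit site ids, for tests and simulations.

    If ``coefficients`` is omitted they are drawn deterministically from
    ``seed`` as standard-normal values (never exactly zero in practice).
    """
    ids = list(site_ids)
    if coefficients is None:
        import numpy as np

        rng = np.random.default_rng(seed)
        coefs = rng.standard_normal(len(ids))
        coefficients = [float(c) if c != 0 else 1.0 for c in coefs]
    return ClockDefinition(
        name=name,
        generation=Generation(generation),
        sites=tuple(zip(ids, coefficients)),
    )
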