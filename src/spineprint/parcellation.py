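"""Region schemes for spinal cord cross-sections and brain networks.

A :class:`ParcellationScheme` is an ordered list of labelled regions; its
order fixes the row/column order of every time-series matrix, FC matrix and
ICC map downstream, so all modules agree on indexing.

The spinal cross-section holds 14 regions per level: three bilateral gray
matter regions (dorsal horn ``dh``, intermediate zone ``iz``, ventral horn
``vh``) and four bilateral white matter regions (spinal lemniscus ``sl``,
corticospinal tract ``cst``, fasciculus cuneatus ``fc``, fasciculus gracilis
``fg``).  The brain scheme holds 100 cortical regions sorted into the seven
canonical resting-state networks plus 19 subcortical regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RegionLabel",
    "ParcellationScheme",
    "build_spinal_scheme",
    "build_brain_scheme",
    "combine_schemes",
    "default_brain_scheme",
    "read_scheme",
    "write_scheme",
    "SPINAL_GM_CODES",
    "SPINAL_WM_CODES",
    "CROSS_SECTION_ORDER",
    "BRAIN_NETWORKS",
]

SPINAL_GM_CODES = ("dh", "iz", "vh")
SPINAL_WM_CODES = ("sl", "cst", "fc", "fg")
SPINAL_CODES = SPINAL_GM_CODES + SPINAL_WM_CODES

#: Canonical within-level order: GM block then WM block, left before right.
CROSS_SECTION_ORDER = tuple(
    (code, side)
    for code in SPINAL_GM_CODES + SPINAL_WM_CODES
    for side in ("L", "R")
)

#: Cortical networks in display order; subcortex (SUB) always last.
BRAIN_NETWORKS = ("VIS", "SM", "DA", "VA", "L", "FP", "DMN")

_LEVEL_RE = re.compile(r"^(C[1-8]|T1)$")


@dataclass(frozen=True)
class RegionLabel:
    """One region: name, tissue class, laterality, and spinal/brain tags."""

    name: str
    structure: str  # "GM" or "WM"
    side: str  # "L", "R" or "NA"
    code: str  # one of the 7 spinal codes, or a free string for brain
    level: str = ""  # spinal level tag such as "C4"; empty for brain
    network: str = ""  # brain network tag; empty for spine

    def __post_init__(self) -> None:
        if self.structure not in ("GM", "WM"):
            raise ValueError(f"structure must be GM or WM, got {self.structure!r}")
        if self.side not in ("L", "R", "NA"):
            raise ValueError(f"side must be L, R or NA, got {self.side!r}")
        if self.level:
            if self.code not in SPINAL_CODES:
                raise ValueError(
                    f"spinal label {self.name!r} has code {self.code!r}, "
                    f"expected one of {SPINAL_CODES}"
                )
            if not _LEVEL_RE.match(self.level):
                raise ValueError(
                    f"level tag {self.level!r} does not match C1-C8/T1"
                )
        elif not self.network:
            raise ValueError(
                f"label {self.name!r} must carry a spinal level or a brain network"
            )


@dataclass(frozen=True)
class ParcellationScheme:
    """Ordered region labels; row order == matrix order everywhere."""

    labels: tuple[RegionLabel, ...]
    kind: str  # "spinal", "brain" or "combined"

    def __post_init__(self) -> None:
        if self.kind not in ("spinal", "brain", "combined"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        names = [lab.name for lab in self.labels]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names in scheme: {dup}")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(lab.name for lab in self.labels)

    @property
    def levels(self) -> tuple[str, ...]:
        """Distinct spinal level tags in scheme order."""
        seen: list[str] = []
        for lab in self.labels:
            if lab.level and lab.level not in seen:
                seen.append(lab.level)
        return tuple(seen)

    def index_of(self, names: Iterable[str]) -> list[int]:
        lookup = {lab.name: i for i, lab in enumerate(self.labels)}
        try:
            return [lookup[n] for n in names]
        except KeyError as exc:
            raise KeyError(f"region {exc.args[0]!r} not in scheme") from None


def build_spinal_scheme(levels: Sequence[str]) -> ParcellationScheme:
    """14-region cross-section replicated over the given spinal levels.

    Levels are kept in the given (rostral-to-caudal) order; within each level
    regions follow :data:`CROSS_SECTION_ORDER`.  Three levels give 42 regions,
    five give 70, seven give 98.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    if len(set(levels)) != len(levels):
        raise ValueError(f"duplicate level tags in {list(levels)}")
    labels = []
    for level in levels:
        for code, side in CROSS_SECTION_ORDER:
            labels.append(
                RegionLabel(
                    name=f"{level}_{code}_{side}",
                    structure="GM" if code in SPINAL_GM_CODES else "WM",
                    side=side,
                    code=code,
                    level=level,
                )
            )
    return ParcellationScheme(labels=tuple(labels), kind="spinal")


def build_brain_scheme(
    cortical: Sequence[tuple[str, str, str]],
    subcortical: Sequence[str],
) -> ParcellationScheme:
    """Brain scheme: 100 cortical regions + 19 subcortical = 119.

    Parameters
    ----------
    cortical
        Exactly 100 ``(name, network, side)`` triples with network in
        :data:`BRAIN_NETWORKS` and side "L" or "R".
    subcortical
        Exactly 19 region names, assigned network "SUB" and side "NA".

    The output is sorted by network (VIS, SM, DA, VA, L, FP, DMN), left
    hemisphere before right within each network, subcortex last.
    """
    if len(cortical) != 100:
        raise ValueError(f"expected 100 cortical regions, got {len(cortical)}")
    if len(subcortical) != 19:
        raise ValueError(f"expected 19 subcortical regions, got {len(subcortical)}")
    net_rank = {net: i for i, net in enumerate(BRAIN_NETWORKS)}
    side_rank = {"L": 0, "R": 1}
    for name, network, side in cortical:
        if network not in net_rank:
            raise ValueError(f"unknown network {network!r} for region {name!r}")
        if side not in side_rank:
            raise ValueError(f"cortical side must be L or R, got {side!r}")
    ordered = sorted(
        enumerate(cortical),
        key=lambda item: (net_rank[item[1][1]], side_rank[item[1][2]], item[0]),
    )
    labels = [
        RegionLabel(name=name, structure="GM", side=side, code="ctx", network=network)
        for _, (name, network, side) in ordered
    ]
    labels += [
        RegionLabel(name=name, structure="GM", side="NA", code="sub", network="SUB")
        for name in subcortical
    ]
    return ParcellationScheme(labels=tuple(labels), kind="brain")


def combine_schemes(
    brain: ParcellationScheme, spine: ParcellationScheme
) -> ParcellationScheme:
    """Concatenate brain then spinal labels into one combined scheme."""
    if brain.kind != "brain" or spine.kind != "spinal":
        raise ValueError(
            f"expected (brain, spinal) schemes, got ({brain.kind}, {spine.kind})"
        )
    clash = set(brain.names) & set(spine.names)
    if clash:
        raise ValueError(f"region name collision between schemes: {sorted(clash)}")
    return ParcellationScheme(labels=brain.labels + spine.labels, kind="combined")


def default_brain_scheme() -> ParcellationScheme:
    """A synthetic 119-region brain scheme for simulations and examples.

    Region names are generated (not taken from any atlas file): 100 cortical
    names spread over the 7 networks with left/right hemispheres, plus 19
    generic subcortical names.
    """
    # 100 = 2 hemispheres x (8+7+7+7+7+7+7) regions over the 7 networks
    per_net = {"VIS": 8, "SM": 7, "DA": 7, "VA": 7, "L": 7, "FP": 7, "DMN": 7}
    cortical = [
        (f"{side}H_{net}_{i + 1}", net, side)
        for net, k in per_net.items()
        for side in ("L", "R")
        for i in range(k)
    ]
    subcortical = [f"SUB_{i + 1}" for i in range(19)]
    return build_brain_scheme(cortical, subcortical)


_SCHEME_HEADER = ["name", "structure", "side", "code", "level", "network"]


def write_scheme(scheme: ParcellationScheme, path: str | Path) -> None:
    """Serialize a scheme to TSV (row order == matrix order)."""
    lines = ["\t".join(_SCHEME_HEADER + ["kind"])]
    for lab in scheme.labels:
        lines.append(
            "\t".join(
                [lab.name, lab.structure, lab.side, lab.code, lab.level,
                 lab.network, scheme.kind]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme(path: str | Path) -> ParcellationScheme:
    """Read a scheme TSV written by :func:`write_scheme`."""
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    if header[:6] != _SCHEME_HEADER:
        raise ValueError(f"unexpected scheme header {header!r} in {path}")
    labels = []
    kind = "combined"
    for line in lines[1:]:
        fields = line.split("\t")
        name, structure, side, code, level, network = (fields + [""] * 6)[:6]
        if len(fields) > 6:
            kind = fields[6]
        labels.append(
            RegionLabel(name=name, structure=structure, side=side, code=code,
                        level=level, network=network)
        )
    return ParcellationScheme(labels=tuple(labels), kind=kind)
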