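"""Categorical calls from raw tumor assay observations.

Three assays feed the Lynch-syndrome triage of an endometrial tumor:

* a five-marker mononucleotide microsatellite panel (BAT26, BAT25, NR21,
  NR24, NR27) scored per marker as stable / unstable / failed;
* mismatch-repair immunohistochemistry for MLH1, MSH2, MSH6 and PMS2,
  scored retained / lost / unreliable (unreliable = no internal positive
  control, i.e. normal tissue failed to stain);
* MS-MLPA methylation ratios for the two MLH1-promoter probes covering the
  C and D promoter regions, measured in tumor and optionally blood.

This module turns those raw observations into the categorical calls the
decision tree consumes: an MSI status, an IHC loss pattern, and a
methylated/unmethylated status at a 15% two-probe-mean threshold.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from statistics import fmean

__all__ = [
    "MarkerStatus",
    "ProteinStatus",
    "Tissue",
    "MsiStatus",
    "MethylationStatus",
    "MsiMarkerPanel",
    "IhcPanel",
    "MethylationMeasurement",
    "MsiCall",
    "IhcPattern",
    "MSI_MARKERS",
    "MMR_PROTEINS",
    "call_msi",
    "call_ihc_pattern",
    "methylation_ratio",
    "call_methylation",
    "DEFAULT_METHYLATION_THRESHOLD",
]

#: Marker names of the mononucleotide MSI panel, in canonical order.
MSI_MARKERS = ("bat26", "bat25", "nr21", "nr24", "nr27")

#: Mismatch-repair proteins assessed by IHC, in canonical order.
MMR_PROTEINS = ("mlh1", "msh2", "msh6", "pms2")

#: Two-probe-mean methylation ratio at or above which a sample is called
#: methylated.
DEFAULT_METHYLATION_THRESHOLD = 0.15

#: MS-MLPA ratios above 1 can occur through normalisation overshoot; ratios
#: beyond this bound are rejected as implausible.
MAX_PROBE_RATIO = 1.5


class MarkerStatus(str, enum.Enum):
    """Per-marker microsatellite result."""

    STABLE = "stable"
    UNSTABLE = "unstable"
    FAILED = "failed"


class ProteinStatus(str, enum.Enum):
    """Per-protein IHC result; UNRELIABLE means no internal control stained."""

    RETAINED = "retained"
    LOST = "lost"
    UNRELIABLE = "unreliable"


class Tissue(str, enum.Enum):
    TUMOR = "tumor"
    BLOOD = "blood"
    NORMAL_ENDOMETRIUM = "normal_endometrium"


class MsiStatus(str, enum.Enum):
    MSI = "MSI"
    MSS = "MSS"
    INDETERMINATE = "indeterminate"


class MethylationStatus(str, enum.Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"


def _coerce(value, enum_cls, what: str):
    if isinstance(value, enum_cls):
        return value
    if isinstance(value, str):
        try:
            return enum_cls(value.strip().lower())
        except ValueError:
            pass
    raise ValueError(
        f"invalid {what} value {value!r}; expected one of "
        f"{[m.value for m in enum_cls]}"
    )


@dataclass(frozen=True)
class MsiMarkerPanel:
    """Raw statuses of the five mononucleotide markers for one tumor.

    String values are accepted case-insensitively and coerced to
    :class:`MarkerStatus`.
    """

    bat26: MarkerStatus
    bat25: MarkerStatus
    nr21: MarkerStatus
    nr24: MarkerStatus
    nr27: MarkerStatus

    def __post_init__(self):
        for name in MSI_MARKERS:
            object.__setattr__(
                self, name, _coerce(getattr(self, name), MarkerStatus, f"marker {name}")
            )

    def statuses(self) -> tuple[MarkerStatus, ...]:
        return tuple(getattr(self, name) for name in MSI_MARKERS)


@dataclass(frozen=True)
class IhcPanel:
    """Raw IHC expression statuses of the four MMR proteins for one tumor."""

    mlh1: ProteinStatus
    msh2: ProteinStatus
    msh6: ProteinStatus
    pms2: ProteinStatus

    def __post_init__(self):
        for name in MMR_PROTEINS:
            object.__setattr__(
                self, name, _coerce(getattr(self, name), ProteinStatus, f"protein {name}")
            )

    def statuses(self) -> dict[str, ProteinStatus]:
        return {name: getattr(self, name) for name in MMR_PROTEINS}


@dataclass(frozen=True)
class MethylationMeasurement:
    """MS-MLPA ratios of the two MLH1-promoter probes for one sample.

    At least one probe ratio must be present.  Ratios are non-negative;
    values above 1 (up to ``MAX_PROBE_RATIO``) are tolerated as
    normalisation overshoot but draw a warning.
    """

    probe_mlh1_3: float | None = None
    probe_mlh1_4: float | None = None
    tissue: Tissue = Tissue.TUMOR

    def __post_init__(self):
        object.__setattr__(self, "tissue", _coerce(self.tissue, Tissue, "tissue"))
        ratios = [self.probe_mlh1_3, self.probe_mlh1_4]
        if all(r is None for r in ratios):
            raise ValueError("methylation measurement requires at least one probe ratio")
        for name, r in zip(("probe_mlh1_3", "probe_mlh1_4"), ratios):
            if r is None:
                continue
            if not (0.0 <= r):
                raise ValueError(f"{name} must be non-negative, got {r}")
            if r > MAX_PROBE_RATIO:
                raise ValueError(
                    f"{name}={r} exceeds the plausible ratio bound {MAX_PROBE_RATIO}"
                )
            if r > 1.0:
                warnings.warn(
                    f"{name}={r} exceeds 1.0 (MS-MLPA normalisation overshoot)",
                    stacklevel=3,
                )

    def available_probes(self) -> tuple[float, ...]:
        return tuple(r for r in (self.probe_mlh1_3, self.probe_mlh1_4) if r is not None)


@dataclass(frozen=True)
class MsiCall:
    """MSI status with the marker counts supporting it."""

    status: MsiStatus
    n_unstable: int
    n_informative: int

    def __post_init__(self):
        if not (0 <= self.n_unstable <= self.n_informative <= len(MSI_MARKERS)):
            raise ValueError(
                f"marker counts inconsistent: n_unstable={self.n_unstable}, "
                f"n_informative={self.n_informative}"
            )


@dataclass(frozen=True)
class IhcPattern:
    """Set of MMR proteins with lost expression, plus an unreliability flag."""

    lost: frozenset[str] = field(default_factory=frozenset)
    any_unreliable: bool = False

    def __post_init__(self):
        canonical = frozenset(p.upper() for p in self.lost)
        allowed = {p.upper() for p in MMR_PROTEINS}
        if not canonical <= allowed:
            raise ValueError(f"unknown proteins in loss set: {sorted(canonical - allowed)}")
        object.__setattr__(self, "lost", canonical)


def call_msi(panel: MsiMarkerPanel, min_informative: int = 3) -> MsiCall:
    """Call microsatellite status from the five-marker panel.

    A tumor is MSI when two or more markers show an altered (unstable)
    pattern.  Failed markers do not count as informative; with fewer than
    ``min_informative`` informative markers and fewer than two unstable
    ones the status is indeterminate rather than MSS, so a mostly-failed
    panel cannot produce a false stable call.
    """
    statuses = panel.statuses()
    n_unstable = sum(s is MarkerStatus.UNSTABLE for s in statuses)
    n_informative = sum(s is not MarkerStatus.FAILED for s in statuses)
    if n_unstable >= 2:
        status = MsiStatus.MSI
    elif n_informative < min_informative:
        status = MsiStatus.INDETERMINATE
    else:
        status = MsiStatus.MSS
    return MsiCall(status=status, n_unstable=n_unstable, n_informative=n_informative)


def call_ihc_pattern(panel: IhcPanel) -> IhcPattern:
    """Summarise the IHC panel as a loss pattern.

    A protein enters the loss set only on a definite LOST call; UNRELIABLE
    stainings (no internal control) never count as loss but set the
    ``any_unreliable`` flag for downstream review.
    """
    statuses = panel.statuses()
    lost = frozenset(
        name.upper() for name, s in statuses.items() if s is ProteinStatus.LOST
    )
    any_unreliable = any(s is ProteinStatus.UNRELIABLE for s in statuses.values())
    return IhcPattern(lost=lost, any_unreliable=any_unreliable)


def methylation_ratio(m: MethylationMeasurement) -> float:
    """Two-probe-mean methylation ratio of a sample.

    The ratio is the arithmetic mean of the available promoter-probe
    ratios; with a single probe present its value is used directly and a
    warning is recorded.
    """
    probes = m.available_probes()
    if len(probes) == 1:
        warnings.warn(
            "methylation ratio computed from a single probe", stacklevel=2
        )
    return fmean(probes)


def call_methylation(
    m: MethylationMeasurement,
    threshold: float = DEFAULT_METHYLATION_THRESHOLD,
) -> MethylationStatus:
    """Call methylated/unmethylated at the two-probe-mean threshold.

    A ratio exactly at the threshold is called methylated (>=), so the
    stated 15% cutoff is itself actionable.
    """
    ratio = methylation_ratio(m)
    if ratio >= threshold:
        return MethylationStatus.METHYLATED
    return MethylationStatus.UNMETHYLATED
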