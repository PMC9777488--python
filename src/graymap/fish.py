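"""2018 ASCO/CAP HER2 FISH grouping and status resolution.

A FISH case is summarized by the mean HER2 signal count per tumor cell, the
mean CEP17 (chromosome-17 centromere) count, and their ratio, averaged over
20 tumor cells.  The (ratio, HER2 copies) plane partitions into five groups:

=====  =========================  ===========================
Group  HER2/CEP17 ratio           mean HER2 copies per cell
=====  =========================  ===========================
G1     >= 2.0                     >= 4.0
G2     >= 2.0                     < 4.0
G3     < 2.0                      >= 6.0
G4     < 2.0                      4.0 <= copies < 6.0
G5     < 2.0                      < 4.0
=====  =========================  ===========================

G1 is FISH positive and G5 negative outright.  The equivocal groups are
resolved with the concurrent IHC score: G2 and G4 are positive only when IHC
is 3+; G3 is negative only when IHC is 0 or 1+.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

__all__ = ["FISHCase", "assign_group", "resolve_status", "classify_case"]

IHC_SCORES = ("0", "1+", "2+", "3+")
GROUPS = ("G1", "G2", "G3", "G4", "G5")


@dataclass(frozen=True)
class FISHCase:
    """Mean HER2/CEP17 signal counts per cell and their ratio."""

    her2_copies: float
    cep17_copies: float
    ratio: float = None

    def __post_init__(self) -> None:
        if self.her2_copies < 0:
            raise ValueError("HER2 copy number must be >= 0")
        if self.cep17_copies <= 0:
            raise ValueError("CEP17 copy number must be > 0")
        computed = self.her2_copies / self.cep17_copies
        if self.ratio is not None and abs(self.ratio - computed) > 1e-6:
            warnings.warn(
                f"provided ratio {self.ratio} disagrees with HER2/CEP17 = "
                f"{computed:.6f}; using the computed value"
            )
        object.__setattr__(self, "ratio", computed)


def assign_group(case: FISHCase) -> str:
    """Assign the ASCO/CAP group G1-G5 from ratio and HER2 copy number."""
    if case.ratio >= 2.0:
        return "G1" if case.her2_copies >= 4.0 else "G2"
    if case.her2_copies >= 6.0:
        return "G3"
    if case.her2_copies >= 4.0:
        return "G4"
    return "G5"


def resolve_status(group: str, ihc: str) -> str:
    """Resolve final HER2 status ("positive"/"negative") from group and IHC.

    G2/G4 require IHC 3+ for positivity; G3 flips negative only for IHC 0/1+
    (for 2+ or 3+ the amplified copy number carries the call).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown FISH group {group!r}")
    if ihc not in IHC_SCORES:
        raise ValueError(f"unknown IHC score {ihc!r}; expected one of {IHC_SCORES}")
    if group == "G1":
        return "positive"
    if group == "G5":
        return "negative"
    if group in ("G2", "G4"):
        return "positive" if ihc == "3+" else "negative"
    # G3
    return "negative" if ihc in ("0", "1+") else "positive"


def classify_case(case: FISHCase, ihc: str) -> tuple[str, str]:
    """Convenience: (group, resolved status) for one case."""
    group = assign_group(case)
    return group, resolve_status(group, ihc)
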