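"""Candidate linkage-region calling and interval export.

A region is a maximal run of consecutive evaluated positions whose averaged
LOD meets a suggestive threshold (1.90 by convention here). Bounds are the
outermost above-threshold evaluated positions themselves, so reported
intervals are marker-delimited; single-position regions are legal. Internal
coordinates are 1-based inclusive bp; BED export converts to 0-based
half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import FileFormatError, ParameterError
from .linkage import LodCurve

__all__ = [
    "LinkageRegion",
    "call_regions",
    "regions_to_bed",
    "bed_to_regions",
    "regions_to_json",
]


@dataclass(frozen=True)
class LinkageRegion:
    """A contiguous above-threshold interval of the averaged LOD curve."""

    chromosome: str
    start_bp: int
    end_bp: int
    start_marker_id: str | None
    end_marker_id: str | None
    max_lod: float
    argmax_bp: int
    argmax_cm: float

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ParameterError(
                f"region start {self.start_bp} > end {self.end_bp} "
                f"on chromosome {self.chromosome}"
            )

    def contains(self, chromosome: str, position_bp: int) -> bool:
        """1-based inclusive membership test."""
        return (
            str(chromosome) == self.chromosome
            and self.start_bp <= position_bp <= self.end_bp
        )

    @property
    def name(self) -> str:
        return f"{self.start_marker_id or self.start_bp}~{self.end_marker_id or self.end_bp}"


def call_regions(curve: LodCurve, threshold: float = 1.90, marker_ids=None):
    """Maximal runs of consecutive positions with mean LOD >= threshold.

    Returns regions ordered by genome position (curve order), each carrying
    its maximum LOD and argmax position. ``marker_ids``, when given, must
    parallel the curve positions and provides boundary marker names.
    """
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    chroms = np.array([str(c) for c in curve.chromosomes])
    regions = []
    for chrom in curve.chromosome_list():
        mask = chroms == chrom
        idx = np.flatnonzero(mask)
        above = curve.mean_lod[idx] >= threshold
        i = 0
        n = len(idx)
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            run = idx[i : j + 1]
            k = run[int(np.argmax(curve.mean_lod[run]))]
            regions.append(
                LinkageRegion(
                    chromosome=chrom,
                    start_bp=int(curve.positions_bp[run[0]]),
                    end_bp=int(curve.positions_bp[run[-1]]),
                    start_marker_id=marker_ids[run[0]] if marker_ids else None,
                    end_marker_id=marker_ids[run[-1]] if marker_ids else None,
                    max_lod=float(curve.mean_lod[k]),
                    argmax_bp=int(curve.positions_bp[k]),
                    argmax_cm=float(curve.positions_cm[k]),
                )
            )
            i = j + 1
    return regions


def regions_to_bed(regions) -> str:
    """BED text (0-based half-open), name = start_marker~end_marker, score = 100*max LOD."""
    lines = ["# pedlink linkage regions (BED: 0-based half-open)"]
    for r in regions:
        lines.append(
            f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{r.name}"
            f"\t{round(100 * r.max_lod)}"
        )
    return "\n".join(lines) + "\n"


def bed_to_regions(bed_text: str):
    """Parse :func:`regions_to_bed` output back into LinkageRegion objects.

    The max LOD is recovered from the score at 0.01 resolution; argmax
    coordinates are not stored in BED and default to the interval start.
    """
    regions = []
    for lineno, ln in enumerate(bed_text.splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 5:
            raise FileFormatError("BED line needs 5 columns", lineno)
        chrom, start0, end, name, score = parts[:5]
        names = name.split("~")
        start_marker = names[0] if len(names) == 2 and not names[0].isdigit() else None
        end_marker = names[1] if len(names) == 2 and not names[1].isdigit() else None
        start_bp = int(start0) + 1
        regions.append(
            LinkageRegion(
                chromosome=chrom,
                start_bp=start_bp,
                end_bp=int(end),
                start_marker_id=start_marker,
                end_marker_id=end_marker,
                max_lod=int(score) / 100.0,
                argmax_bp=start_bp,
                argmax_cm=float("nan"),
            )
        )
    return regions


def regions_to_json(regions) -> str:
    return json.dumps(
        [
            {
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "start_marker_id": r.start_marker_id,
                "end_marker_id": r.end_marker_id,
                "max_lod": r.max_lod,
                "argmax_bp": r.argmax_bp,
                "argmax_cm": r.argmax_cm,
            }
            for r in regions
        ],
        indent=2,
    )
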