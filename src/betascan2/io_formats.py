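"""Reading and writing the allele-count scan format.

Input files are plain text (optionally gzip-compressed) with one site per
line and at least three whitespace- or tab-separated integer columns::

    position    allele_count    sample_size

Positions are 1-based and must strictly increase within a file.  In
unfolded files the count is the *derived* allele count and a site fixed
for the derived allele relative to the outgroup (a substitution) is
encoded as ``count == sample_size``.  In folded files the count is the
minor-allele count; substitutions cannot be represented, and counts above
``n/2`` are folded down on input.  Extra columns are ignored (with a
single warning per file); a leading header line, detected by a
non-integer first field, is skipped.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, List, Optional, Sequence, Union

logger = logging.getLogger("betascan2")

POLYMORPHIC = "polymorphic"
SUBSTITUTION = "substitution"


class BetaScanError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(BetaScanError):
    """A line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(ParseError):
    """A parsed record violates a field invariant."""


class OrderingError(ParseError):
    """Positions are not strictly increasing."""


@dataclass(frozen=True)
class SiteRecord:
    """One observed site.

    Attributes
    ----------
    position:
        1-based genomic coordinate in bp.
    count:
        Observed allele copies: derived count if unfolded, minor-allele
        count if folded.
    n:
        Number of chromosomes sampled at this site.
    folded:
        True if ``count`` is a minor-allele count (ancestral state
        unknown); such records cannot encode substitutions.
    """

    position: int
    count: int
    n: int
    folded: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"sample size must be >= 2, got {self.n}")
        if not (1 <= self.count <= self.n):
            raise ValidationError(
                f"count must satisfy 1 <= count <= n, got count={self.count}, n={self.n}"
            )
        if self.folded and self.count > self.n // 2:
            raise ValidationError(
                f"folded count must be <= n/2, got count={self.count}, n={self.n}"
            )

    @property
    def is_substitution(self) -> bool:
        return not self.folded and self.count == self.n

    @property
    def freq(self) -> float:
        """Allele frequency count/n (derived or minor depending on mode)."""
        return self.count / self.n

    @property
    def folded_freq(self) -> float:
        """Minor-allele frequency min(count, n - count)/n."""
        return min(self.count, self.n - self.count) / self.n


def classify_site(rec: SiteRecord) -> str:
    """Classify an unfolded record as ``polymorphic`` or ``substitution``.

    Folded records carry no substitution concept and are rejected.
    """
    if rec.folded:
        raise ValidationError("folded records cannot be classified (no substitution concept)")
    return SUBSTITUTION if rec.count == rec.n else POLYMORPHIC


def _open_text(source: Union[str, IO[str], Iterable[str]]) -> Iterable[str]:
    if isinstance(source, str):
        if source.endswith(".gz"):
            return io.TextIOWrapper(gzip.open(source, "rb"), encoding="utf-8")
        return open(source, "r", encoding="utf-8")
    return source


def read_sites(
    source: Union[str, IO[str], Iterable[str]], folded: bool = False
) -> List[SiteRecord]:
    """Parse a scan-format stream into a position-sorted list of records.

    Parameters
    ----------
    source:
        A file path (``.gz`` transparently decompressed), an open text
        stream, or any iterable of lines.
    folded:
        Interpret counts as minor-allele counts.  Counts above ``n/2``
        are folded to ``n - count``; ``count == n`` is an error since a
        folded file cannot encode substitutions.

    Raises
    ------
    ParseError, ValidationError, OrderingError
        With the offending 1-based line number in the message.
    """
    lines = _open_text(source)
    records: List[SiteRecord] = []
    last_pos: Optional[int] = None
    warned_extra = False
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(
                    f"expected >= 3 fields (position, count, n), got {len(fields)}", lineno
                )
            if len(fields) > 3 and not warned_extra:
                logger.warning("line %d: ignoring extra columns beyond the first 3", lineno)
                warned_extra = True
            try:
                position, count, n = (int(fields[0]), int(fields[1]), int(fields[2]))
            except ValueError:
                if lineno == 1 and not records:
                    # tolerated header line
                    continue
                raise ParseError(f"non-integer field in {fields[:3]!r}", lineno) from None
            if folded:
                if n >= 2 and count == n:
                    raise ValidationError(
                        "folded input cannot encode substitutions (count == n)", lineno
                    )
                if 0 < count < n:
                    count = min(count, n - count)
            try:
                rec = SiteRecord(position=position, count=count, n=n, folded=folded)
            except ValidationError as err:
                raise ValidationError(str(err), lineno) from None
            if last_pos is not None and position <= last_pos:
                kind = "duplicate" if position == last_pos else "non-increasing"
                raise OrderingError(f"{kind} position {position}", lineno)
            last_pos = position
            records.append(rec)
    finally:
        if hasattr(lines, "close") and lines is not source:
            lines.close()  # type: ignore[union-attr]
    return records


def write_sites(records: Sequence[SiteRecord], stream: IO[str]) -> None:
    """Write records in the three-column scan format (no header)."""
    for rec in records:
        stream.write(f"{rec.position}\t{rec.count}\t{rec.n}\n")


@dataclass(frozen=True)
class ScoreRow:
    """One scored core SNP (or locus).

    ``beta`` is the raw statistic in per-window mutation-rate units,
    ``variance`` its model variance (same units squared) and ``beta_std``
    the dimensionless standardized score ``beta / sqrt(variance)``.
    ``percentile`` is the optional empirical genome-wide percentile
    (midrank) computed over all emitted rows.
    """

    position: int
    statistic_name: str
    beta: float
    variance: float
    beta_std: float
    percentile: Optional[float] = None

    def __post_init__(self) -> None:
        if self.statistic_name not in ("B1", "B1star", "B2"):
            raise ValidationError(f"unknown statistic name {self.statistic_name!r}")
        if not self.variance > 0:
            raise ValidationError(f"variance must be > 0, got {self.variance}")
        if not math.isclose(
            self.beta_std, self.beta / math.sqrt(self.variance), rel_tol=1e-9, abs_tol=1e-12
        ):
            raise ValidationError("beta_std must equal beta / sqrt(variance)")


SCORE_HEADER = "position\tbeta\tvariance\tbeta_std"


def write_scores(
    rows: Sequence[ScoreRow], stream: IO[str], percentiles: bool = False
) -> None:
    """Write a score table: tab-separated, fixed header, >= 6 sig. digits."""
    header = SCORE_HEADER + ("\tpercentile" if percentiles else "")
    stream.write(header + "\n")
    for row in rows:
        line = (
            f"{row.position}\t{row.beta:.6g}\t{row.variance:.6g}\t{row.beta_std:.6g}"
        )
        if percentiles:
            line += f"\t{row.percentile:.6g}"
        stream.write(line + "\n")


def read_scores(
    source: Union[str, IO[str], Iterable[str]], statistic_name: str = "B2"
) -> List[ScoreRow]:
    """Read back a table written by :func:`write_scores`."""
    lines = _open_text(source)
    rows: List[ScoreRow] = []
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "position":
                continue
            try:
                position = int(fields[0])
                beta, variance, beta_std = (float(f) for f in fields[1:4])
                percentile = float(fields[4]) if len(fields) > 4 else None
            except (ValueError, IndexError):
                raise ParseError(f"malformed score row {line!r}", lineno) from None
            # reconstruct beta_std from the rounded fields so the invariant
            # check tolerates 6-digit output rounding
            rows.append(
                ScoreRow(
                    position=position,
                    statistic_name=statistic_name,
                    beta=beta,
                    variance=variance,
                    beta_std=beta / math.sqrt(variance),
                    percentile=percentile,
                )
            )
            if not math.isclose(rows[-1].beta_std, beta_std, rel_tol=1e-4, abs_tol=1e-9):
                raise ValidationError("inconsistent beta_std column", lineno)
    finally:
        if hasattr(lines, "close") and lines is not source:
            lines.close()  # type: ignore[union-attr]
    return rows
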