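"""Readers and writers for SEQUEST-era spectrum and result files.

Three formats are handled:

* ``.dta`` — one spectrum per file: a header line with the singly-protonated
  precursor mass (M+H) and charge, then whitespace-delimited m/z–intensity
  pairs. Blank lines and ``#`` comments are ignored.
* ``.out`` — one SEQUEST search result per spectrum. SEQUEST text output
  varies across versions, so one minimal dialect is supported (documented on
  :func:`read_out`); the fixture files generated by :mod:`pival.synth` define
  the contract bit-exactly.
* ``pix`` — the XML result format bundling SEQUEST scores, the PI similarity
  score and protein references per PSM.
"""

from __future__ import annotations

import os
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .masses import PROTON


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass(frozen=True)
class Peak:
    """One experimental peak: m/z in Thomson, non-negative intensity."""

    mz: float
    intensity: float

    def __post_init__(self):
        if not self.mz > 0:
            raise ValueError(f"peak mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Spectrum:
    """An experimental peak list with its precursor mass and charge."""

    source_id: str
    precursor_mh: float
    charge: int
    peaks: list[Peak]

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if not self.precursor_mh > PROTON:
            raise ValueError("precursor M+H must exceed the proton mass")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)


@dataclass
class SequestHit:
    """One ranked candidate peptide from a SEQUEST ``.out`` file.

    ``delta_cn`` is the gap applicable to this hit: by the SEQUEST convention
    the value printed on row i+1 is the relative score drop from row i's
    XCorr, so the parser re-assigns it (see :func:`read_out`).
    """

    rank: int
    peptide: str
    flank_prev: str
    flank_next: str
    xcorr: float
    delta_cn: float
    sp: Optional[float]
    proteins: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.xcorr < 0:
            raise ValueError("xcorr must be >= 0")
        if not 0.0 <= self.delta_cn <= 1.0:
            raise ValueError("delta_cn must lie in [0, 1]")


@dataclass
class SequestOut:
    """Parsed content of one ``.out`` file."""

    spectrum_id: str
    precursor_mh: float
    charge: int
    hits: list[SequestHit]


@dataclass
class PSM:
    """One candidate peptide assigned to one spectrum."""

    spectrum: Spectrum
    hit: SequestHit
    pi_score: Optional[float] = None
    is_decoy: bool = False

    def __post_init__(self):
        if self.pi_score is not None and not 0.0 <= self.pi_score <= 1.0:
            raise ValueError("pi_score must lie in [0, 1]")


@dataclass
class PixRecord:
    """One validated PSM as stored in the pix file."""

    spectrum_id: str
    peptide: str
    xcorr: float
    delta_cn: float
    sp: Optional[float]
    pi_score: float
    proteins: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# .dta

def read_dta(path: str | os.PathLike) -> Spectrum:
    """Read one ``.dta`` spectrum file.

    Line 1 holds the singly-protonated precursor mass and charge; every
    following non-blank, non-comment line holds one ``mz intensity`` pair.
    Peaks are returned sorted ascending by m/z.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    content = [
        (i + 1, ln.split("#", 1)[0].strip())
        for i, ln in enumerate(lines)
    ]
    content = [(n, ln) for n, ln in content if ln]
    if not content:
        raise FormatError(f"{path}: empty file")
    header_no, header = content[0]
    fields = header.split()
    if len(fields) != 2:
        raise FormatError(f"{path}: line {header_no}: header must hold 'M+H charge'")
    try:
        mh = float(fields[0])
        charge = int(fields[1])
    except ValueError as exc:
        raise FormatError(f"{path}: line {header_no}: malformed header {header!r}") from exc
    peaks = []
    for n, ln in content[1:]:
        parts = ln.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: line {n}: expected 'mz intensity', got {ln!r}")
        try:
            peaks.append(Peak(float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise FormatError(f"{path}: line {n}: bad peak {ln!r}") from exc
    if not peaks:
        raise FormatError(f"{path}: no peaks found after the header")
    return Spectrum(source_id=path.stem, precursor_mh=mh, charge=charge, peaks=peaks)


def write_dta(spectrum: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum in ``.dta`` format (6 decimal places)."""
    lines = [f"{spectrum.precursor_mh:.6f} {spectrum.charge}"]
    lines += [f"{p.mz:.6f} {p.intensity:.6f}" for p in spectrum.peaks]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# .out

_HIT_HEADER_RE = re.compile(r"\bRank\b.*\bXCorr\b", re.IGNORECASE)
_PEPTIDE_TOKEN_RE = re.compile(r"^(?:([A-Z\-])\.)?([A-Z]+)(?:\.([A-Z\-]))?$")


def strip_flanks(token: str) -> tuple[str, str, str]:
    """Split ``K.PEPTIDER.A`` into (peptide, previous flank, next flank).

    A bare peptide with no flank notation gets '-' on both sides.
    """
    m = _PEPTIDE_TOKEN_RE.match(token)
    if not m:
        raise FormatError(f"unparseable peptide token {token!r}")
    prev, pep, nxt = m.groups()
    return pep, prev or "-", nxt or "-"


def read_out(path: str | os.PathLike) -> SequestOut:
    """Read one SEQUEST ``.out`` file in the supported minimal dialect.

    The dialect: free-form header lines, one of which contains
    ``(M+H)+ mass = <m> ... charge = <z>``; then a table header line
    containing the words ``Rank`` and ``XCorr`` (optionally followed by a
    dashed rule), then one whitespace-delimited row per candidate with
    columns::

        rank  (M+H)+  deltCn  XCorr  Sp  ions  reference  peptide

    ``reference`` may be a comma-separated list of protein identifiers; the
    peptide uses the flanking notation ``K.PEPTIDER.A``. The deltCn printed
    on row i+1 is the relative XCorr gap below row i, so the hit stored for
    rank i carries row i+1's printed value; the last hit gets 1.0.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    mh = charge = None
    header_idx = None
    for i, ln in enumerate(lines):
        m = re.search(r"\(M\+H\)\+\s*mass\s*=\s*([0-9.]+).*charge\s*=\s*(\d+)", ln)
        if m:
            mh, charge = float(m.group(1)), int(m.group(2))
        if _HIT_HEADER_RE.search(ln):
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(f"{path}: no candidate table found (header with Rank/XCorr)")
    rows = []
    for n, ln in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        stripped = ln.strip()
        if not stripped:
            if rows:
                break
            continue
        if set(stripped) <= set("- "):
            continue
        rows.append((n, stripped))
    if not rows:
        raise FormatError(f"{path}: candidate table has no rows")

    parsed = []
    for n, row in rows:
        parts = row.split()
        if len(parts) < 8:
            raise FormatError(f"{path}: line {n}: expected 8 columns, got {len(parts)}: {row!r}")
        try:
            rank = int(parts[0].rstrip("."))
            row_mh = float(parts[1])
            printed_dcn = float(parts[2])
            xcorr = float(parts[3])
            sp = float(parts[4])
        except ValueError as exc:
            raise FormatError(f"{path}: line {n}: unparseable score field in {row!r}") from exc
        proteins = [p for p in parts[6].split(",") if p]
        peptide, prev, nxt = strip_flanks(parts[7])
        parsed.append((rank, row_mh, printed_dcn, xcorr, sp, proteins, peptide, prev, nxt))

    hits = []
    for i, (rank, row_mh, _dcn, xcorr, sp, proteins, pep, prev, nxt) in enumerate(parsed):
        # deltCn applicable to this hit is printed on the next row
        dcn = parsed[i + 1][2] if i + 1 < len(parsed) else 1.0
        hits.append(SequestHit(
            rank=rank, peptide=pep, flank_prev=prev, flank_next=nxt,
            xcorr=xcorr, delta_cn=min(max(dcn, 0.0), 1.0), sp=sp, proteins=proteins,
        ))
    if mh is None:
        mh = parsed[0][1]
    if charge is None:
        charge = 2
    return SequestOut(spectrum_id=path.stem, precursor_mh=mh, charge=charge, hits=hits)


def is_decoy_hit(hit: SequestHit, decoy_prefix: str = "rev_") -> bool:
    """A hit is a decoy iff any protein reference starts with the prefix."""
    return any(p.startswith(decoy_prefix) for p in hit.proteins)


def pair_inputs(
    directory: str | os.PathLike,
    decoy_prefix: str = "rev_",
    top_n: int = 1,
) -> list[PSM]:
    """Pair ``.dta`` and ``.out`` files by basename into PSMs.

    By default only the rank-1 hit of each ``.out`` becomes a PSM. Files
    without a partner are reported with a warning, never fatally.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"input directory not found: {directory}")
    dtas = {p.stem: p for p in sorted(directory.glob("*.dta"))}
    outs = {p.stem: p for p in sorted(directory.glob("*.out"))}
    for stem in sorted(set(dtas) ^ set(outs)):
        kind = ".dta" if stem in dtas else ".out"
        warnings.warn(f"unpaired {kind} file for basename {stem!r}", stacklevel=2)
    psms = []
    for stem in sorted(set(dtas) & set(outs)):
        spectrum = read_dta(dtas[stem])
        out = read_out(outs[stem])
        for hit in out.hits[:top_n]:
            psms.append(PSM(
                spectrum=spectrum,
                hit=hit,
                is_decoy=is_decoy_hit(hit, decoy_prefix),
            ))
    if not psms:
        warnings.warn(f"no .dta/.out pairs found in {directory}", stacklevel=2)
    return psms


# ---------------------------------------------------------------------------
# pix XML

def _fmt(x: float) -> str:
    # shortest representation that round-trips the float exactly
    return repr(float(x))


def write_pix(
    records: Sequence[PixRecord],
    path: str | os.PathLike,
    meta: Optional[dict] = None,
) -> None:
    """Write pix XML: per-PSM SEQUEST scores, PI score and protein references.

    Schema: ``<pix><meta .../><psm id=..><peptide/><xcorr/><deltacn/><sp/>
    <piscore/><proteins><ref/>..</proteins></psm>..</pix>``.
    """
    if not records:
        raise ValueError("refusing to write a pix file with no records")
    root = ET.Element("pix")
    if meta:
        ET.SubElement(root, "meta", {k: str(v) for k, v in sorted(meta.items())})
    for rec in records:
        psm = ET.SubElement(root, "psm", {"id": rec.spectrum_id})
        ET.SubElement(psm, "peptide").text = rec.peptide
        ET.SubElement(psm, "xcorr").text = _fmt(rec.xcorr)
        ET.SubElement(psm, "deltacn").text = _fmt(rec.delta_cn)
        ET.SubElement(psm, "sp").text = "" if rec.sp is None else _fmt(rec.sp)
        ET.SubElement(psm, "piscore").text = _fmt(rec.pi_score)
        prots = ET.SubElement(psm, "proteins")
        for ref in rec.proteins:
            ET.SubElement(prots, "ref").text = ref
    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def read_pix(path: str | os.PathLike) -> list[PixRecord]:
    """Read a pix XML file back into records."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed pix XML: {exc}") from exc
    if root.tag != "pix":
        raise FormatError(f"{path}: root element is <{root.tag}>, expected <pix>")
    records = []
    for psm in root.findall("psm"):
        sp_text = psm.findtext("sp", default="")
        records.append(PixRecord(
            spectrum_id=psm.get("id", ""),
            peptide=psm.findtext("peptide", default=""),
            xcorr=float(psm.findtext("xcorr")),
            delta_cn=float(psm.findtext("deltacn")),
            sp=float(sp_text) if sp_text.strip() else None,
            pi_score=float(psm.findtext("piscore")),
            proteins=[r.text or "" for r in psm.findall("proteins/ref")],
        ))
    return records


def read_pix_meta(path: str | os.PathLike) -> dict:
    root = ET.parse(path).getroot()
    meta = root.find("meta")
    return dict(meta.attrib) if meta is not None else {}
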