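"""LC-MS run I/O, chromatogram extraction and ppm peak matching.

Runs are lists of centroided :class:`Scan` objects.  Two on-disk formats are
supported: mzML (compact lxml-based reader covering centroid spectra with
64/32-bit float arrays, zlib or uncompressed; written by the minimal
serializer here) and a plain TSV peak-list dialect with columns
``rt, ms_level, precursor_mz, mz, intensity`` for human-readable fixtures.

Retention times are minutes everywhere; RT intervals are half-open
[start, end).
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "Scan",
    "EIC",
    "read_run",
    "write_mzml",
    "write_peak_tsv",
    "read_peak_tsv",
    "match_peak",
    "extract_eic",
    "validate_rt",
    "assign_prm_scans",
    "DEFAULT_MS1_TOL_PPM",
    "DEFAULT_MS2_TOL_PPM",
]

DEFAULT_MS1_TOL_PPM = 5.0
DEFAULT_MS2_TOL_PPM = 10.0


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Scan:
    """One centroided mass spectrum.  Peaks are kept mz-sorted."""

    ms_level: int
    rt: float                      # minutes
    polarity: str = "+"
    precursor_mz: float | None = None
    isolation_width: float = 1.0   # Th, MS2 only
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 scan requires a precursor m/z")

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]


@dataclass
class EIC:
    """Extracted ion chromatogram of one target m/z."""

    target_mz: float
    tolerance_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    @property
    def apex_rt(self) -> float | None:
        if len(self.rt) == 0 or np.all(self.intensity == 0):
            return None
        return float(self.rt[int(np.argmax(self.intensity))])

    @property
    def apex_intensity(self) -> float:
        return float(np.max(self.intensity)) if len(self.intensity) else 0.0

    @property
    def area(self) -> float:
        if len(self.rt) < 2:
            return 0.0
        return float(np.trapezoid(self.intensity, self.rt))


# ---------------------------------------------------------------------------
# Peak matching and EICs
# ---------------------------------------------------------------------------

def ppm_error(observed: float, target: float) -> float:
    return (observed - target) / target * 1e6


def match_peak(scan: Scan, target_mz: float, tol_ppm: float) -> Peak | None:
    """Most intense peak within ``tol_ppm`` of ``target_mz`` (inclusive)."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    tol = target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(scan.mz, target_mz - tol, side="left")
    hi = np.searchsorted(scan.mz, target_mz + tol, side="right")
    if lo == hi:
        return None
    k = lo + int(np.argmax(scan.intensity[lo:hi]))
    return Peak(float(scan.mz[k]), float(scan.intensity[k]))


def matched_intensity(scan: Scan, target_mz: float, tol_ppm: float) -> float:
    """Summed intensity of all in-tolerance peaks (for EICs)."""
    tol = target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(scan.mz, target_mz - tol, side="left")
    hi = np.searchsorted(scan.mz, target_mz + tol, side="right")
    return float(np.sum(scan.intensity[lo:hi]))


def extract_eic(
    scans: Iterable[Scan],
    target_mz: float,
    tol_ppm: float = DEFAULT_MS1_TOL_PPM,
    rt_range: tuple[float, float] | None = None,
    ms_level: int = 1,
) -> EIC:
    """Per-scan summed in-tolerance intensity over retention time.

    Coeluting targets closer than the tolerance are summed together; this is
    deliberate (the tolerance defines the extraction window).
    """
    picked = sorted(
        (s for s in scans if s.ms_level == ms_level
         and (rt_range is None or rt_range[0] <= s.rt < rt_range[1])),
        key=lambda s: s.rt,
    )
    rts = np.array([s.rt for s in picked])
    vals = np.array([matched_intensity(s, target_mz, tol_ppm) for s in picked])
    return EIC(target_mz, tol_ppm, rts, vals)


def validate_rt(
    scans: Sequence[Scan],
    precursor_mz: float,
    expected_rt: float,
    window: float = 1.0,
    tol_ppm: float = DEFAULT_MS1_TOL_PPM,
    noise_floor: float = 0.0,
) -> tuple[bool, float | None]:
    """Check that the precursor EIC apex falls within expected_rt +/- window.

    Returns (passed, apex_rt).  Fails with apex None when the precursor is
    absent or never exceeds the noise floor.
    """
    eic = extract_eic(scans, precursor_mz, tol_ppm)
    apex = eic.apex_rt
    if apex is None or eic.apex_intensity <= noise_floor:
        return False, None
    return abs(apex - expected_rt) <= window, apex


def assign_prm_scans(
    scans: Iterable[Scan],
    target_mz: float,
    rt_range: tuple[float, float],
) -> list[Scan]:
    """MS2 scans belonging to a PRM target: precursor within the isolation
    half-width and RT inside the target window; ties go to the nearest
    precursor (a scan is claimed only by its closest matching target)."""
    out = []
    for s in scans:
        if s.ms_level != 2 or s.precursor_mz is None:
            continue
        if not rt_range[0] <= s.rt < rt_range[1]:
            continue
        if abs(s.precursor_mz - target_mz) <= s.isolation_width / 2:
            out.append(s)
    return sorted(out, key=lambda s: s.rt)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="run">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(scans: Sequence[Scan], path: str | Path) -> None:
    """Serialize scans as minimal centroid mzML (uncompressed 64-bit arrays)."""
    parts = [_MZML_HEADER.format(count=len(scans))]
    for i, s in enumerate(scans):
        pol_acc, pol_name = (
            ("MS:1000130", "positive scan") if s.polarity == "+"
            else ("MS:1000129", "negative scan")
        )
        mz_b64 = _encode_array(s.mz)
        it_b64 = _encode_array(s.intensity)
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" '
            f'defaultArrayLength="{len(s.mz)}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" '
            f'name="ms level" value="{s.ms_level}"/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000127" '
            f'name="centroid spectrum" value=""/>\n'
            f'        <cvParam cvRef="MS" accession="{pol_acc}" '
            f'name="{pol_name}" value=""/>\n'
            f'        <scanList count="1">\n'
            f'          <scan>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000016" '
            f'name="scan start time" value="{s.rt!r}" unitCvRef="UO" '
            f'unitAccession="UO:0000031" unitName="minute"/>\n'
            f'          </scan>\n'
            f'        </scanList>\n'
        )
        if s.ms_level == 2:
            half = s.isolation_width / 2
            parts.append(
                f'        <precursorList count="1">\n'
                f'          <precursor>\n'
                f'            <isolationWindow>\n'
                f'              <cvParam cvRef="MS" accession="MS:1000827" '
                f'name="isolation window target m/z" value="{s.precursor_mz!r}"/>\n'
                f'              <cvParam cvRef="MS" accession="MS:1000828" '
                f'name="isolation window lower offset" value="{half!r}"/>\n'
                f'              <cvParam cvRef="MS" accession="MS:1000829" '
                f'name="isolation window upper offset" value="{half!r}"/>\n'
                f'            </isolationWindow>\n'
                f'            <selectedIonList count="1">\n'
                f'              <selectedIon>\n'
                f'                <cvParam cvRef="MS" accession="MS:1000744" '
                f'name="selected ion m/z" value="{s.precursor_mz!r}"/>\n'
                f'              </selectedIon>\n'
                f'            </selectedIonList>\n'
                f'            <activation>\n'
                f'              <cvParam cvRef="MS" accession="MS:1000422" '
                f'name="beam-type collision-induced dissociation" value=""/>\n'
                f'            </activation>\n'
                f'          </precursor>\n'
                f'        </precursorList>\n'
            )
        parts.append(
            f'        <binaryDataArrayList count="2">\n'
            f'          <binaryDataArray encodedLength="{len(mz_b64)}">\n'
            f'            <cvParam cvRef="MS" accession="MS:1000523" '
            f'name="64-bit float" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000576" '
            f'name="no compression" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000514" '
            f'name="m/z array" value=""/>\n'
            f'            <binary>{mz_b64}</binary>\n'
            f'          </binaryDataArray>\n'
            f'          <binaryDataArray encodedLength="{len(it_b64)}">\n'
            f'            <cvParam cvRef="MS" accession="MS:1000523" '
            f'name="64-bit float" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000576" '
            f'name="no compression" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000515" '
            f'name="intensity array" value=""/>\n'
            f'            <binary>{it_b64}</binary>\n'
            f'          </binaryDataArray>\n'
            f'        </binaryDataArrayList>\n'
            f'      </spectrum>\n'
        )
    Path(path).write_text("".join(parts) + _MZML_FOOTER)


def _decode_binary(elem) -> np.ndarray:
    """Decode one <binaryDataArray> (64/32-bit float, zlib or none)."""
    params = {cv.get("name") for cv in elem.iter("{*}cvParam")}
    binary = elem.find("{*}binary")
    raw = base64.b64decode(binary.text or "")
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Scan]:
    """Parse centroid mzML.  Profile-mode spectra are rejected."""
    from lxml import etree

    scans: list[Scan] = []
    try:
        context = etree.iterparse(str(path), events=("end",), tag="{*}spectrum")
        for _, spec in context:
            params = {
                cv.get("name"): cv
                for cv in spec.iterchildren("{*}cvParam")
            }
            if "profile spectrum" in params:
                raise ValueError(
                    f"{path}: profile-mode spectra are not supported; "
                    "centroid the data first"
                )
            level = int(params["ms level"].get("value", 1)) \
                if "ms level" in params else 1
            polarity = "-" if "negative scan" in params else "+"
            rt_min = 0.0
            scan_el = spec.find("{*}scanList/{*}scan")
            if scan_el is not None:
                for cv in scan_el.iterchildren("{*}cvParam"):
                    if cv.get("name") == "scan start time":
                        rt_min = float(cv.get("value"))
                        if "second" in (cv.get("unitName") or "minute"):
                            rt_min /= 60.0
            precursor, iso_width = None, 1.0
            prec_el = spec.find("{*}precursorList/{*}precursor")
            if prec_el is not None:
                vals = {
                    cv.get("name"): float(cv.get("value"))
                    for cv in prec_el.iter("{*}cvParam")
                    if cv.get("value") not in (None, "")
                }
                precursor = vals.get(
                    "isolation window target m/z", vals.get("selected ion m/z")
                )
                iso_width = (
                    vals.get("isolation window lower offset", 0.5)
                    + vals.get("isolation window upper offset", 0.5)
                )
            mz_arr = np.empty(0)
            it_arr = np.empty(0)
            for bda in spec.iter("{*}binaryDataArray"):
                names = {cv.get("name") for cv in bda.iter("{*}cvParam")}
                if "m/z array" in names:
                    mz_arr = _decode_binary(bda)
                elif "intensity array" in names:
                    it_arr = _decode_binary(bda)
            scans.append(Scan(
                ms_level=level,
                rt=rt_min,
                polarity=polarity,
                precursor_mz=precursor,
                isolation_width=iso_width,
                mz=mz_arr,
                intensity=it_arr,
            ))
            spec.clear()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: unreadable mzML ({exc})") from exc
    return scans


# ---------------------------------------------------------------------------
# TSV peak-list dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["scan", "rt", "ms_level", "polarity", "precursor_mz",
                "isolation_width", "mz", "intensity"]


def write_peak_tsv(scans: Sequence[Scan], path: str | Path) -> None:
    """Write the human-readable TSV dialect (one row per peak)."""
    rows = []
    for i, s in enumerate(scans):
        if len(s.mz) == 0:
            rows.append((i, s.rt, s.ms_level, s.polarity,
                         s.precursor_mz, s.isolation_width, np.nan, np.nan))
        for m, it in zip(s.mz, s.intensity):
            rows.append((i, s.rt, s.ms_level, s.polarity,
                         s.precursor_mz, s.isolation_width, m, it))
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_peak_tsv(path: str | Path) -> list[Scan]:
    df = pd.read_csv(path, sep="\t")
    scans = []
    for _, grp in df.groupby("scan", sort=True):
        first = grp.iloc[0]
        peaks = grp.dropna(subset=["mz"])
        precursor = first["precursor_mz"]
        scans.append(Scan(
            ms_level=int(first["ms_level"]),
            rt=float(first["rt"]),
            polarity=str(first["polarity"]),
            precursor_mz=None if pd.isna(precursor) else float(precursor),
            isolation_width=float(first["isolation_width"])
            if pd.notna(first["isolation_width"]) else 1.0,
            mz=peaks["mz"].to_numpy(),
            intensity=peaks["intensity"].to_numpy(),
        ))
    return scans


def read_run(path: str | Path) -> list[Scan]:
    """Read an LC-MS run (mzML, or the TSV peak-list dialect by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        return read_peak_tsv(path)
    return _read_mzml(path)
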