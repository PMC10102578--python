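"""File formats: scan-table TSV, minimal mzML, matrix and cohort tables.

The mzML support is a deliberately small profile-mode subset (one run, one
spectrum list, m/z + intensity binary arrays, 32/64-bit floats, optional
zlib) sufficient for round-tripping simulated recordings.
"""
from __future__ import annotations

import base64

import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScanSeries",
    "read_scan_table",
    "write_scan_table",
    "read_mzml",
    "write_mzml",
    "read_recording",
    "write_matrix",
    "read_matrix",
    "write_cohort",
    "read_cohort",
]

MZ_MIN = 50.0
MZ_MAX = 500.0


@dataclass
class ScanSeries:
    """One participant's raw recording: ordered scans of (time, m/z, intensity)."""

    times: np.ndarray  # seconds, strictly increasing
    mz_arrays: list[np.ndarray]  # each ascending, within [50, 500]
    intensity_arrays: list[np.ndarray]  # each >= 0
    polarity: str = "positive"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.mz_arrays) or len(self.times) != len(
            self.intensity_arrays
        ):
            raise ValueError("times, mz_arrays and intensity_arrays must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("scan times must be strictly increasing")
        for mz, inten in zip(self.mz_arrays, self.intensity_arrays):
            if len(mz) != len(inten):
                raise ValueError("mz and intensity arrays must have equal length")
            if len(mz) and (mz[0] < MZ_MIN - 1e-9 or mz[-1] > MZ_MAX + 1e-9):
                raise ValueError("m/z values must lie within [50, 500]")
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError("mz arrays must be strictly ascending")
            if len(inten) and np.min(inten) < 0:
                raise ValueError("intensities must be >= 0")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")

    def __len__(self) -> int:
        return len(self.times)

    def tic(self) -> np.ndarray:
        """Per-scan total ion current (sum of raw intensities)."""
        return np.array([float(np.sum(i)) for i in self.intensity_arrays])


# ---------------------------------------------------------------------------
# plain scan-table TSV
# ---------------------------------------------------------------------------


def write_scan_table(series: ScanSeries, path: str | Path) -> None:
    """Write a recording as a long TSV: scan_index, time_s, mz, intensity."""
    frames = []
    for k, (t, mz, inten) in enumerate(
        zip(series.times, series.mz_arrays, series.intensity_arrays)
    ):
        frames.append(
            pd.DataFrame(
                {
                    "scan_index": k,
                    "time_s": t,
                    "mz": mz,
                    "intensity": inten,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["scan_index", "time_s", "mz", "intensity"]
    )
    with open(path, "w") as fh:
        fh.write(f"# polarity={series.polarity}\tsample_id={series.sample_id}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_scan_table(path: str | Path) -> ScanSeries:
    polarity, sample_id = "positive", Path(path).stem
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].strip().split("\t"):
                if tok.startswith("polarity="):
                    polarity = tok.split("=", 1)[1]
                elif tok.startswith("sample_id="):
                    sample_id = tok.split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t")
        else:
            df = pd.read_csv(path, sep="\t")
    times, mzs, intens = [], [], []
    for _, grp in df.groupby("scan_index", sort=True):
        times.append(float(grp["time_s"].iloc[0]))
        order = np.argsort(grp["mz"].to_numpy())
        mzs.append(grp["mz"].to_numpy()[order])
        intens.append(grp["intensity"].to_numpy()[order])
    return ScanSeries(np.array(times), mzs, intens, polarity=polarity, sample_id=sample_id)


# ---------------------------------------------------------------------------
# minimal mzML
# ---------------------------------------------------------------------------

_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray, compress: bool) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(series: ScanSeries, path: str | Path, compress: bool = False) -> None:
    """Write a profile-mode mzML file (subset of the PSI schema)."""
    mzml = ET.Element("mzML", xmlns=_NS, version="1.1.0")
    run = ET.SubElement(mzml, "run", id=series.sample_id or "run")
    slist = ET.SubElement(run, "spectrumList", count=str(len(series)))
    pol_acc = "MS:1000130" if series.polarity == "positive" else "MS:1000129"
    pol_name = "positive scan" if series.polarity == "positive" else "negative scan"
    for k, (t, mz, inten) in enumerate(
        zip(series.times, series.mz_arrays, series.intensity_arrays)
    ):
        spec = ET.SubElement(
            slist, "spectrum", index=str(k), id=f"scan={k+1}", defaultArrayLength=str(len(mz))
        )
        ET.SubElement(spec, "cvParam", accession="MS:1000128", name="profile spectrum")
        ET.SubElement(spec, "cvParam", accession=pol_acc, name=pol_name)
        scan_list = ET.SubElement(spec, "scanList", count="1")
        scan = ET.SubElement(scan_list, "scan")
        ET.SubElement(
            scan,
            "cvParam",
            accession="MS:1000016",
            name="scan start time",
            value=repr(float(t)),
            unitName="second",
        )
        arrs = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for acc, name, vals in (
            ("MS:1000514", "m/z array", mz),
            ("MS:1000515", "intensity array", inten),
        ):
            bda = ET.SubElement(arrs, "binaryDataArray")
            ET.SubElement(bda, "cvParam", accession="MS:1000523", name="64-bit float")
            ET.SubElement(
                bda,
                "cvParam",
                accession="MS:1000574" if compress else "MS:1000576",
                name="zlib compression" if compress else "no compression",
            )
            ET.SubElement(bda, "cvParam", accession=acc, name=name)
            ET.SubElement(bda, "binary").text = _encode_array(vals, compress)
    ET.indent(mzml)
    ET.ElementTree(mzml).write(path, xml_declaration=True, encoding="utf-8")


def _decode_array(bda: ET.Element) -> np.ndarray:
    accs = {cv.get("accession") for cv in bda.iter(f"{{{_NS}}}cvParam")} | {
        cv.get("accession") for cv in bda.iter("cvParam")
    }
    binary = bda.find(f"{{{_NS}}}binary")
    if binary is None:
        binary = bda.find("binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> ScanSeries:
    tree = ET.parse(path)
    root = tree.getroot()

    def findall(el, tag):
        return el.iter(f"{{{_NS}}}{tag}") if root.tag.startswith("{") else el.iter(tag)

    polarity = "positive"
    times, mzs, intens = [], [], []
    for spec in findall(root, "spectrum"):
        t = 0.0
        for cv in findall(spec, "cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000129":
                polarity = "negative"
            elif acc == "MS:1000130":
                polarity = "positive"
            elif acc == "MS:1000016":
                t = float(cv.get("value", "0"))
                if cv.get("unitName", "second").startswith("min"):
                    t *= 60.0
        mz_arr = inten_arr = np.array([])
        for bda in findall(spec, "binaryDataArray"):
            accs = {cv.get("accession") for cv in findall(bda, "cvParam")}
            vals = _decode_array(bda)
            if "MS:1000514" in accs:
                mz_arr = vals
            elif "MS:1000515" in accs:
                inten_arr = vals
        times.append(t)
        mzs.append(mz_arr)
        intens.append(inten_arr)
    run = next(iter(findall(root, "run")), None)
    sid = run.get("id") if run is not None else Path(path).stem
    return ScanSeries(np.array(times), mzs, intens, polarity=polarity, sample_id=sid)


def read_recording(path: str | Path) -> ScanSeries:
    """Dispatch on extension: .mzML or scan-table TSV."""
    p = Path(path)
    if p.suffix.lower() == ".mzml":
        return read_mzml(p)
    return read_scan_table(p)


# ---------------------------------------------------------------------------
# matrices and cohort tables
# ---------------------------------------------------------------------------


def write_matrix(values: np.ndarray, feature_mz, sample_ids, path: str | Path) -> None:
    """Samples x features TSV with a header row of consensus m/z values."""
    df = pd.DataFrame(
        np.asarray(values), index=list(sample_ids), columns=[f"{m:.6f}" for m in feature_mz]
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    feature_mz = np.array([float(c) for c in df.columns])
    return df.to_numpy(dtype=float), feature_mz, [str(s) for s in df.index]


def write_cohort(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
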