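"""Minimal mzML 1.1.0 writer and reader for centroided spectra.

The writer emits uncompressed 64-bit little-endian peak arrays with the
controlled-vocabulary terms readers require (ms level, centroid
spectrum, scan start time in minutes, precursor selected-ion
annotations); output is a pure function of the spectrum list, so
identical inputs give byte-identical files. The reader handles the
standard binary-array encodings (32/64-bit float, optional zlib) and
minute/second time units, which covers files produced by mainstream
converters as well as this writer.
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path
from typing import List, Optional, Sequence
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

from .features import Spectrum

__all__ = ["write_mzml", "read_mzml"]

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="gslprof" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="gslprof"/>
    </dataProcessing>
  </dataProcessingList>
"""


def _encode(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


def _binary_array(values: np.ndarray, kind: str) -> str:
    data = _encode(values)
    if kind == "mz":
        name = '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
    else:
        name = '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
    return (
        f'          <binaryDataArray encodedLength="{len(data)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f"            {name}\n"
        f"            <binary>{data}</binary>\n"
        "          </binaryDataArray>\n"
    )


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra (sorted by retention time) to an mzML file."""
    parts = [_HEADER]
    parts.append('  <run id="run1" defaultInstrumentConfigurationRef="IC1">\n')
    parts.append(f'    <spectrumList count="{len(spectra)}" defaultDataProcessingRef="DP1">\n')
    for index, s in enumerate(spectra):
        level_param = (
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
            if s.ms_level == 1
            else '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
        )
        parts.append(
            f'      <spectrum index="{index}" id="{escape(s.scan_id)}" defaultArrayLength="{s.mz.size}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>\n'
            f"        {level_param}\n"
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            '        <scanList count="1">\n'
            "          <scan>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.retention_time:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
        )
        if s.ms_level == 2 and s.precursor_mz is not None:
            charge = (
                f'                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{s.precursor_charge}"/>\n'
                if s.precursor_charge
                else ""
            )
            parts.append(
                '        <precursorList count="1">\n'
                "          <precursor>\n"
                '            <selectedIonList count="1">\n'
                "              <selectedIon>\n"
                f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
                f"{charge}"
                "              </selectedIon>\n"
                "            </selectedIonList>\n"
                "          </precursor>\n"
                "        </precursorList>\n"
            )
        parts.append('        <binaryDataArrayList count="2">\n')
        parts.append(_binary_array(s.mz, "mz"))
        parts.append(_binary_array(s.intensity, "intensity"))
        parts.append("        </binaryDataArrayList>\n      </spectrum>\n")
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    Path(path).write_text("".join(parts))


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(array_elem):
    dtype = "<f8"
    compressed = False
    kind = None
    text = ""
    for child in array_elem.iter():
        tag = _strip(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif tag == "binary":
            text = child.text or ""
    raw = base64.b64decode(text) if text else b""
    if compressed and raw:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> List[Spectrum]:
    """Read a centroided mzML file into Spectrum objects (rt in minutes)."""
    spectra: List[Spectrum] = []
    for _, elem in ElementTree.iterparse(str(path), events=("end",)):
        if _strip(elem.tag) != "spectrum":
            continue
        ms_level = 1
        rt = 0.0
        prec_mz: Optional[float] = None
        prec_z: Optional[int] = None
        mz = np.empty(0)
        intensity = np.empty(0)
        for child in elem.iter():
            tag = _strip(child.tag)
            if tag == "cvParam":
                acc = child.get("accession", "")
                if acc == "MS:1000511":
                    ms_level = int(child.get("value", "1"))
                elif acc == "MS:1000016":
                    rt = float(child.get("value", "0"))
                    unit = child.get("unitName", "minute")
                    if "second" in unit:
                        rt /= 60.0
                elif acc == "MS:1000744":
                    prec_mz = float(child.get("value", "0"))
                elif acc == "MS:1000041":
                    prec_z = int(child.get("value", "0")) or None
            elif tag == "binaryDataArray":
                kind, values = _decode_binary(child)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    intensity = values
        spectra.append(
            Spectrum(
                scan_id=elem.get("id", f"index={elem.get('index', '?')}"),
                ms_level=ms_level,
                retention_time=rt,
                mz=mz,
                intensity=intensity,
                precursor_mz=prec_mz,
                precursor_charge=prec_z,
            )
        )
        elem.clear()
    spectra.sort(key=lambda s: s.retention_time)
    return spectra
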