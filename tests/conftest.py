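"""Shared fixtures: reference records, annotation config, synthetic mzML."""

import base64
import struct

import pytest

from saponet import AnnotationConfig, load_fixtures
from saponet.decompose import default_aglycones


@pytest.fixture(scope="session")
def records():
    return load_fixtures()


@pytest.fixture(scope="session")
def records_by_no(records):
    return {r.number: r for r in records}


@pytest.fixture()
def config():
    return AnnotationConfig()


@pytest.fixture(scope="session")
def aglycone_by_name():
    return {a.name: a for a in default_aglycones()}


def _b64_doubles(values):
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def write_minimal_mzml(spectra, path, profile=False):
    """Write a minimal synthetic mzML file (MS2 scans only) that a
    standards-compliant reader can parse; used to exercise read_mzml."""
    blocks = []
    for i, s in enumerate(spectra):
        mzs, intens = s.mzs, s.intensities
        mode = ("MS:1000128\" name=\"profile spectrum" if profile
                else "MS:1000127\" name=\"centroid spectrum")
        polarity_acc = ("MS:1000129\" name=\"negative scan" if s.polarity == "negative"
                        else "MS:1000130\" name=\"positive scan")
        rt = s.rt if s.rt is not None else 0.0
        blocks.append(f"""
   <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mzs)}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
    <cvParam cvRef="MS" accession="{mode}" value=""/>
    <cvParam cvRef="MS" accession="{polarity_acc}" value=""/>
    <scanList count="1">
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
     </scan>
    </scanList>
    <precursorList count="1">
     <precursor>
      <selectedIonList count="1">
       <selectedIon>
        <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
       </selectedIon>
      </selectedIonList>
     </precursor>
    </precursorList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{len(_b64_doubles(mzs))}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
      <binary>{_b64_doubles(mzs)}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{len(_b64_doubles(intens))}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
      <binary>{_b64_doubles(intens)}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>""")
    body = "".join(blocks)
    text = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <run id="synthetic">
  <spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp">{body}
  </spectrumList>
 </run>
</mzML>
"""
    with open(path, "w") as fh:
        fh.write(text)
    return path
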