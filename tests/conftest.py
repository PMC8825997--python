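"""Shared fixtures: the bundled compound library and small synthetic inputs."""

import base64

import numpy as np
import pytest

from derep_ms.peaks import bundled_library, bundled_library_table


@pytest.fixture(scope="session")
def library():
    return bundled_library()


@pytest.fixture(scope="session")
def library_table():
    return bundled_library_table()


@pytest.fixture(scope="session")
def library_by_name(library):
    return {c.name: c for c in library}


def _encode_f8(values) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


@pytest.fixture
def tiny_mzml(tmp_path):
    """A minimal centroided single-spectrum mzML file (positive mode)."""
    mzs = [127.0755, 459.14032]
    intensities = [1000.0, 2000.0]
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r1">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="2">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="2.19" unitName="minute"/>
        </scan></scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{_encode_f8(mzs)}</binary>
          </binaryDataArray>
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{_encode_f8(intensities)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>"""
    path = tmp_path / "tiny.mzML"
    path.write_text(doc, encoding="utf-8")
    return path
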