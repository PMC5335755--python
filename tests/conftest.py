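import base64

import numpy as np
import pytest

from disms2 import MatchParams, Run, Spectrum, SyntheticConfig, generate_dataset


def make_spectrum(mz, intensity=None, scan=1, precursor=500.0, charge=2, rt=None):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    return Spectrum(scan_number=scan, precursor_mz=precursor,
                    precursor_charge=charge, mz=mz, intensity=intensity,
                    retention_time=rt)


def random_spectrum(rng, n_peaks=None, scan=1, charge=2):
    if n_peaks is None:
        n_peaks = int(rng.integers(3, 12))
    mz = np.sort(rng.uniform(100, 1200, size=n_peaks))
    intensity = rng.exponential(100.0, size=n_peaks) + 1e-6
    return Spectrum(scan_number=scan, precursor_mz=float(rng.uniform(300, 1200)),
                    precursor_charge=charge, mz=mz, intensity=intensity)


def mzml_document(spectra):
    """Minimal mzML 1.1 text for a list of spectrum description dicts.

    Each dict: scan, ms_level, mz, intensity, and for MS2 prec_mz plus
    optional charge and rt_sec/rt_min.
    """

    def b64(arr):
        return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()

    blocks = []
    for i, sp in enumerate(spectra):
        pre = ""
        if sp["ms_level"] == 2:
            charge = sp.get("charge")
            charge_cv = (f'<cvParam cvRef="MS" accession="MS:1000041" '
                         f'name="charge state" value="{charge}"/>' if charge else "")
            pre = (
                '<precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>'
                f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
                f'value="{sp["prec_mz"]}" unitCvRef="MS" unitAccession="MS:1000040" '
                f'unitName="m/z"/>{charge_cv}'
                '</selectedIon></selectedIonList></precursor></precursorList>')
        rt = ""
        if "rt_sec" in sp:
            rt = (f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
                  f'value="{sp["rt_sec"]}" unitName="second"/>')
        elif "rt_min" in sp:
            rt = (f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
                  f'value="{sp["rt_min"]}" unitName="minute"/>')
        blocks.append(f'''<spectrum index="{i}" id="scan={sp["scan"]}" defaultArrayLength="{len(sp["mz"])}">
  <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{sp["ms_level"]}"/>
  <scanList count="1"><scan>{rt}</scan></scanList>
  {pre}
  <binaryDataArrayList count="2">
    <binaryDataArray encodedLength="0">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
      <binary>{b64(sp["mz"])}</binary>
    </binaryDataArray>
    <binaryDataArray encodedLength="0">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <binary>{b64(sp["intensity"])}</binary>
    </binaryDataArray>
  </binaryDataArrayList>
</spectrum>''')
    return f'''<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="fixture">
    <spectrumList count="{len(spectra)}">
      {''.join(blocks)}
    </spectrumList>
  </run>
</mzML>'''


@pytest.fixture(scope="session")
def default_params():
    return MatchParams()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default study conditions: 3 species x 3 technical replicates."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Faster variant for tests that only need structure, not power."""
    cfg = SyntheticConfig(seed=5, spectra_per_run=40,
                          peaks_per_spectrum=(10, 25))
    return generate_dataset(cfg)
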