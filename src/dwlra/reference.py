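"""Bundled reference measurements from a published two-scan liver
DW-MRI reproducibility study (five fasted volunteers, each scanned twice
within two weeks, single selected slice and ROI per scan).

Four small tables ship with the package:

* ``adc_histogram_widths`` — ADC-histogram width sigma_D per dataset for
  six processing variants (PA: on-scanner averaged protocol; AVG: plain
  average of the separately stored repeats; LRA: local-rigid alignment;
  NRA: deformable registration; LRA-b / AVG-b: Gaussian-blurred
  variants), units 1e-5 mm^2/s.
* ``mean_adc`` — mean ROI ADC per dataset and variant, 1e-5 mm^2/s.
* ``width_reduction`` — the published signed quadrature differences of
  AVG width vs each corrected variant.
* ``reproducibility`` — the published between-scan percentage change in
  mean ADC per volunteer and variant.

The first two are measurement inputs: the evaluation statistics in
:mod:`dwlra.metrics` recompute the last two from them, which is the
package's worked consistency check.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "adc_histogram_widths",
    "mean_adc",
    "width_reduction",
    "reproducibility_table",
    "SCAN_PAIRS",
    "PUBLISHED_MEAN_DELTA_D",
    "PUBLISHED_MEAN_DELTA_SIGMA",
]

#: the two scan sessions of each volunteer, keyed by reproducibility-pair id
SCAN_PAIRS = {
    "v1-0503-0515": ("v1-0503", "v1-0515"),
    "v2-0521-0528": ("v2-0521", "v2-0528"),
    "v3-0524-0528": ("v3-0524", "v3-0528"),
    "v4-0611-0614": ("v4-0611", "v4-0614"),
    "v5-0731-0809": ("v5-0731", "v5-0809"),
}

#: published per-method means of the reproducibility table (%)
PUBLISHED_MEAN_DELTA_D = {
    "PA": 6.11, "AVG": 3.93, "LRA": 3.27,
    "NRA": 1.87, "LRA-b": 3.12, "AVG-b": 3.98,
}

#: published per-method means of the width-reduction table (1e-5 mm^2/s)
PUBLISHED_MEAN_DELTA_SIGMA = {
    "LRA": 14.03, "NRA": 8.48, "LRA-b": 23.29, "AVG-b": 15.88,
}


def _load(name: str, index_col: str) -> pd.DataFrame:
    with resources.files("dwlra.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, index_col=index_col)


def adc_histogram_widths() -> pd.DataFrame:
    """sigma_D per dataset and method variant (1e-5 mm^2/s)."""
    return _load("adc_histogram_widths.csv", "dataset")


def mean_adc() -> pd.DataFrame:
    """Mean ROI ADC per dataset and method variant (1e-5 mm^2/s)."""
    return _load("mean_adc.csv", "dataset")


def width_reduction() -> pd.DataFrame:
    """Published signed quadrature width differences vs AVG."""
    return _load("width_reduction.csv", "dataset")


def reproducibility_table() -> pd.DataFrame:
    """Published between-scan percentage change in mean ADC."""
    return _load("reproducibility.csv", "pair")
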