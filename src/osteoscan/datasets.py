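"""Bundled reference dataset of paired BV/TV measurements.

Ten osteochondral plugs harvested from femoral heads of hip-osteoarthritis
patients, each measured twice: subchondral trabecular BV/TV (%) from
micro-CT (75–255 binarization window) and from the dual-sequence micro-MRI
method, plus the marrow fat-to-water ratio (mean proton-density fat
fraction) from the MRI pair.  The per-sample values come from a published
micro-CT/micro-MRI method-comparison study and serve as the canonical
worked example for :func:`osteoscan.agreement.bland_altman`; they cannot be
recomputed here because the underlying scans are not distributed.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_paired_bvtv"]

_PAIRED_BVTV_CSV = """\
sample_id,ct_bvtv,mri_bvtv,mri_fat_to_water
K-F1,26.851,30.480,0.693
K-F2,33.258,34.856,0.795
K-F3,34.248,26.499,0.790
K-F4,21.135,15.667,0.710
K-F5,13.027,20.539,0.519
K-F6,22.066,19.965,0.690
K-F7,24.064,19.400,0.368
K-F8,25.026,17.659,0.430
K-F9,33.319,23.141,0.649
K-F10,19.923,23.043,0.623
"""


def load_paired_bvtv() -> pd.DataFrame:
    """Paired per-sample BV/TV (%) by micro-CT and micro-MRI.

    Returns a DataFrame with columns ``sample_id``, ``ct_bvtv``,
    ``mri_bvtv`` and ``mri_fat_to_water``.
    """
    return pd.read_csv(io.StringIO(_PAIRED_BVTV_CSV))
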