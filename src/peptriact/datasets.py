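"""Bundled example data: corn germ meal hydrolysis optimization and peptides.

A published optimization study of alkaline-protease hydrolysis of corn
germ meal provides a complete worked dataset for this package: a
17-run three-factor Box-Behnken experiment (enzyme dosage, hydrolysis
time, solid-liquid ratio) with four measured responses, and the three
corn peptides that survived the downstream virtual-screening funnel,
with their MS metadata and external predictor scores.  The tables are
embedded verbatim so that every stage of the pipeline can be exercised
and checked against the study's reported statistics without any
external files.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .pepscreen import PeptideRecord
from .rsm import DesignTable, FactorSpec, code_point

__all__ = [
    "CORN_FACTORS",
    "CORN_RESPONSES",
    "CORN_OPTIMUM_ACTUAL",
    "load_corn_design",
    "load_corn_peptides",
]

# Factor levels of the corn hydrolysis Box-Behnken experiment.
CORN_FACTORS = (
    FactorSpec("enzyme_dosage_pct", 1.0, 1.25, 1.5),
    FactorSpec("hydrolysis_time_h", 1.5, 2.25, 3.0),
    FactorSpec("solid_liquid_ratio_pct", 20.0, 27.5, 35.0),
)

#: Response columns: degree of hydrolysis, DPPH scavenging, ADH activation,
#: XOD inhibition -- all in percent.
CORN_RESPONSES = ("DH", "DPPH", "ADH", "XOD")

#: Process optimum reported for this dataset (actual units: %, h, %).
CORN_OPTIMUM_ACTUAL = (1.35, 2.30, 27.44)

_CORN_DESIGN_CSV = """\
enzyme_dosage_pct,hydrolysis_time_h,solid_liquid_ratio_pct,DH,DPPH,ADH,XOD
1.25,2.25,27.5,47.28,53.25,11.75,46.25
1.25,2.25,27.5,46.34,66.81,12.51,44.7
1.5,3,27.5,54.88,12.97,7.74,10.07
1.25,2.25,27.5,48.1,64.49,11.27,44.44
1.25,2.25,27.5,44.17,59.78,16.13,50.39
1.25,3,35,48.99,25.18,9.26,13.67
1.25,1.5,20,24.55,29.36,10.14,13.88
1.25,2.25,27.5,45.18,62.33,14.78,58.72
1.5,1.5,27.5,34.93,13.76,2.18,14.58
1,2.25,35,54.21,27.74,10.95,17.52
1,2.25,20,40.61,15.95,1.92,3.05
1.25,3,20,40.19,22.62,3.05,20.26
1.5,2.25,35,56.54,14.74,6.92,22.62
1,3,27.5,46.72,17.44,1.89,16.61
1.5,2.25,20,44.72,14.69,9.51,18.49
1,1.5,27.5,32.55,24.79,7.31,17.58
1.25,1.5,35,40.37,22.47,4.28,16.83
"""

_CORN_PEPTIDES = [
    # sequence, observed MS mass (Da), retention time (min), peak area,
    # bioactivity score, toxicity label, solubility label
    ("LMFP", 928.0, 17.3264, 6.40e5, 0.967304, "Non-Toxin", "good"),
    ("FEGLFR", 767.87, 13.9416, 1.38e5, 0.8536, "Non-Toxin", "good"),
    ("QLPSYR", 762.85, 9.3308, 5.54e6, 0.525549, "Non-Toxin", "good"),
]


def load_corn_design() -> DesignTable:
    """The 17-run corn hydrolysis Box-Behnken design with measured responses."""
    frame = pd.read_csv(io.StringIO(_CORN_DESIGN_CSV))
    actual = frame.iloc[:, :3].to_numpy(float)
    coded = np.array([code_point(CORN_FACTORS, row) for row in actual])
    responses = {name: frame[name].to_numpy(float) for name in CORN_RESPONSES}
    return DesignTable(CORN_FACTORS, coded, actual, responses)


def load_corn_peptides() -> list[PeptideRecord]:
    """The three corn peptides surviving the study's screening funnel.

    ALC values above the 80% cut-off were reported only in aggregate for
    these peptides; they are carried here as 90% so the funnel can be run
    end to end.
    """
    return [
        PeptideRecord(
            sequence=seq,
            observed_mass=mass,
            alc=90.0,
            retention_time=rt,
            peak_area=area,
            external_scores={"bioactivity": score, "toxicity": tox, "solubility": sol},
        )
        for seq, mass, rt, area, score, tox, sol in _CORN_PEPTIDES
    ]
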