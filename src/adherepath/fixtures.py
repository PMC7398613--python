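"""Packaged calibration fixtures.

``hird_table23.json`` carries the published cohort moments for the ten
claims-derived study variables (N = 37 359 commercially insured adults with
persistent asthma, observed April 2018 – March 2019): means and medians,
SDs, and the covariance matrix *as printed* — including its small
row/column transcription asymmetries, which callers resolve explicitly via
:func:`adherepath.ssd.symmetrize`.

``trustr_laterals.json`` carries the assumed moments of the two
externally sourced nudge variables (rewards in $/month, engagement rate in
messages/month) and their assumed cross-covariances.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .lateralize import LateralVariable
from .ssd import SummaryDataset, symmetrize


def _load(name: str) -> dict:
    with resources.files("adherepath.data").joinpath(name).open() as fh:
        return json.load(fh)


def hird_ssd(symmetrized: bool = False) -> SummaryDataset:
    """The ten-variable cohort SSD (N = 37 359).

    With ``symmetrized=False`` the covariance is returned exactly as
    printed (asymmetric in the PCP row); ``symmetrized=True`` averages the
    triangles.
    """
    raw = _load("hird_table23.json")
    ssd = SummaryDataset(
        names=raw["names"], n=raw["n"],
        means=np.asarray(raw["means"], dtype=float),
        sds=np.asarray(raw["sds"], dtype=float),
        cov=np.asarray(raw["cov"], dtype=float),
    )
    if symmetrized:
        ssd, _ = symmetrize(ssd)
    return ssd


def hird_medians() -> dict[str, float]:
    raw = _load("hird_table23.json")
    return dict(zip(raw["names"], raw["medians"]))


def hird_pct_nonzero() -> dict[str, float]:
    """Published share of patients with a nonzero count, per count variable."""
    return dict(_load("hird_table23.json")["pct_nonzero"])


def hird_length_of_stay() -> dict[str, float]:
    """Descriptive inpatient length-of-stay moments (hospitalized patients only)."""
    return dict(_load("hird_table23.json")["length_of_stay"])


def trustr_laterals() -> dict[str, LateralVariable]:
    """The rewards and engagement-rate lateral variables with assumed moments."""
    raw = _load("trustr_laterals.json")
    return {
        name: LateralVariable(
            name=name, mean=spec["mean"], sd=spec["sd"],
            cross_cov=dict(spec["cross_cov"]), units=spec.get("units", ""),
        )
        for name, spec in raw.items()
    }
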