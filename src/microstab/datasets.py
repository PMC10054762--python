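"""Packaged reference tables from the published selpercatinib/HLM study.

These are the printed summary tables (replicate means, SDs, nominal
levels) of the original report, shipped so the worked example and the
reproduction checks run from in-repo inputs. Raw replicate-level peak
areas were never published; anything replicate-level must be simulated
(see :mod:`microstab.simulate`).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_depletion_means",
    "load_backcalc_levels",
    "load_qc_batches",
    "load_matrix_effect",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("microstab.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_depletion_means() -> pd.DataFrame:
    """Depletion time course: mean concentration (ng/mL) of three
    replicates at ten stop times, 0-70 min."""
    return _read("selpercatinib_depletion_means.csv")


def load_backcalc_levels() -> pd.DataFrame:
    """Back-calculation summary of six replicates at eleven standards."""
    return _read("selpercatinib_backcalc_levels.csv")


def load_qc_batches() -> pd.DataFrame:
    """Intra-/inter-batch QC means and SDs at the four QC levels."""
    return _read("selpercatinib_qc_batches.csv")


def load_matrix_effect() -> pd.DataFrame:
    """Reported analyte and IS matrix effects (%) with their SDs."""
    return _read("selpercatinib_matrix_effect.csv")
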