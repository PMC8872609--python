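"""Bundled blood-supply-chain case-study data.

A published risk-screening exercise on the Iranian blood supply chain:
a register of 102 coded risks across 22 chain segments, the per-risk
degree-centrality scores from the expert relation network, and the
structural self-interaction matrix the expert panel filled in for the
17 key risks (degree >= 36). These files drive the worked example and
the regression tests.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .ism import SSIM, parse_ssim
from .network import CentralityTable, load_centrality
from .register import RiskRegister, parse_register

#: cutoff that reproduces the case study's 17-risk key set
BSC_KEY_RISK_THRESHOLD = 36


def _data(name: str) -> Path:
    return Path(str(files("ismrisk").joinpath("data", name)))


def load_bsc_register() -> RiskRegister:
    """The 102-risk blood-supply-chain register."""
    return parse_register(_data("bsc_risks.tsv"))


def load_bsc_degrees() -> CentralityTable:
    """Degree-centrality scores for all 102 risks."""
    return load_centrality(_data("bsc_degrees.csv"))


def load_bsc_ssim() -> SSIM:
    """Expert SSIM over the 17 key risks, in its elicitation order."""
    import warnings

    from .errors import GlyphSubstitutionWarning

    with warnings.catch_warnings():
        # the printed table mixes the digit 0 with the letter O
        warnings.simplefilter("ignore", GlyphSubstitutionWarning)
        return parse_ssim(_data("bsc_ssim.csv"))


def bsc_paths() -> dict[str, Path]:
    """Paths of the bundled delimited files, for CLI use."""
    return {
        "register": _data("bsc_risks.tsv"),
        "degrees": _data("bsc_degrees.csv"),
        "ssim": _data("bsc_ssim.csv"),
    }
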