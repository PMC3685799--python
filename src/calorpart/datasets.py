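"""Reference worked-example data.

Published least-squares means from a growing-pig energy-balance
experiment comparing entire males (EM), surgically castrated (SC) and
immunocastrated (IC) littermates (n = 18; six groups of three; mean BW
~115 kg; 6 fed days + 1 fasting day per animal in 12-m3 open-circuit
respiration chambers).  These group-level numbers are the package's
worked example: the standardization algebra applied to them must
reproduce the derived cells (HI, RE_c, ME_m, FD_c, group averages)
without any individual-animal data.

Energy traits are kJ/kg BW^0.60 per day unless noted.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["example_lsmeans", "example_gain_lsmeans"]


def example_lsmeans() -> pd.DataFrame:
    """Energy-balance LS-means by sex class (columns EM, SC, IC)."""
    rows = {
        "bw_kg": (114.0, 111.0, 120.1),
        "standing_h_per_day": (1.6, 1.3, 1.3),
        "me": (2396.0, 2632.0, 2864.0),
        "fhp": (856.0, 735.0, 783.0),
        "ahp": (218.0, 212.0, 250.0),
        "ahp_c": (207.0, 227.0, 247.0),
        "tef_c": (315.0, 464.0, 484.0),
        "hp_c": (1376.0, 1416.0, 1519.0),
        "ahp_pct_me": (9.2, 8.0, 8.7),
        "ahp_c_pct_me": (8.6, 8.6, 8.6),
        "tef_c_pct_me": (13.0, 17.5, 16.9),
        "hi_c_pct_me": (21.6, 26.2, 25.6),
        "rq": (1.08, 1.14, 1.15),
        "me_content_mj_kg_dm": (15.41, 15.37, 15.13),
        "ne_content_mj_kg_dm": (12.02, 11.42, 11.25),
    }
    return pd.DataFrame(rows, index=["EM", "SC", "IC"]).T


def example_gain_lsmeans() -> pd.DataFrame:
    """Growth and deposition LS-means by sex class."""
    rows = {
        "bw_gain_g_per_day": (1370.0, 1133.0, 1317.0),
        "pd_g_per_day": (261.0, 196.0, 246.0),
        "fd_c_g_per_day": (288.0, 403.0, 454.0),
    }
    return pd.DataFrame(rows, index=["EM", "SC", "IC"]).T
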