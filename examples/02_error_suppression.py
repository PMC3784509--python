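"""Show how each error class is removed at its proper consensus stage.

* sequencing errors — independent per read: removed by the SSCS majority;
* late PCR errors — shared by a sub-lineage of one family: mostly removed at
  SSCS, always by duplex agreement;
* single-strand damage — present in ALL reads of one strand family, so it
  passes the SSCS untouched and is removed only by the duplex (DCS) step.

Run:  python examples/02_error_suppression.py
"""

import tempfile
from pathlib import Path

from duplexmt.pipeline import RunConfig, run_full

SCENARIOS = {
    "sequencing only": {"sequencing_error_rate": 2e-3},
    "late PCR only": {"late_pcr_error_rate": 2e-3},
    "damage only": {"damage_error_rate": 2e-3},
    "all three": {
        "sequencing_error_rate": 2e-3,
        "late_pcr_error_rate": 2e-3,
        "damage_error_rate": 2e-3,
    },
}

print(f"{'scenario':>16} | {'raw':>9} | {'SSCS':>9} | {'DCS':>9} | calls")
print("-" * 64)
for name, rates in SCENARIOS.items():
    with tempfile.TemporaryDirectory() as tmp:
        cfg = RunConfig(
            mode="full", output_dir=str(Path(tmp) / "run"), seed=42,
            simulation={
                "n_fragments": 500,
                "family_size_distribution": ["fixed", 5],
                **rates,
            },
        )
        summary = run_full(cfg)
        mm = summary.statistics["mismatch_rates"]
        print(
            f"{name:>16} | {mm['raw']:9.2e} | {mm['sscs']:9.2e} | "
            f"{mm['dcs']:9.2e} | {summary.statistics['n_calls']}"
        )

print(
    "\nNote the ordering raw >= SSCS >= DCS in every scenario, and that\n"
    "damage leaks through the SSCS (it is strand-consistent) but never\n"
    "through the duplex comparison."
)
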