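"""Serial mediation: coupling -> joint control -> dSI -> dPS -> dSC.

Reads results/scores.csv, fits the three-mediator chain on z-scored
variables with a 5000-resample percentile bootstrap, and writes the seven
indirect paths with CIs to results/mediation.csv (paths to
results/mediation.json).
"""

import json
import sys
from pathlib import Path

import numpy as np

from interbrain.io import RunConfig, read_scores_csv
from interbrain.stats import serial_mediation

RESULTS = Path(__file__).resolve().parents[1] / "results"

NAMES = {"X": "coupling", "M1": "joint_control", "M2": "dSI",
         "M3": "dPS", "Y": "dSC"}


def main() -> int:
    config = RunConfig.from_yaml(RESULTS / "config.yaml")
    df = read_scores_csv(RESULTS / "scores.csv")
    med = serial_mediation(
        df["coupling_band"], df["joint_control"],
        df["si_post"] - df["si_pre"], df["ps_post"] - df["ps_pre"],
        df["sc_post"] - df["sc_pre"],
        n_boot=config.n_boot,
        seed=int(config.substream_seed("bootstrap")
                 .generate_state(1, np.uint32)[0]) & 0x7FFFFFFF,
        names=NAMES)

    med.indirect.to_csv(RESULTS / "mediation.csv", index=False)
    (RESULTS / "mediation.json").write_text(json.dumps(
        {"paths": med.paths, "n": med.n, "n_boot": med.n_boot,
         "indirect": med.indirect.to_dict(orient="records")}, indent=2))

    print(f"n = {med.n} dyads, {med.n_boot} bootstrap resamples")
    print(med.indirect.round(4).to_string(index=False))
    sig = med.indirect[(med.indirect.ci_low > 0) | (med.indirect.ci_high < 0)]
    print("paths whose 95% CI excludes zero:",
          sig["label"].tolist() or "none")
    print(f"total c = {med.paths['c']:.4f}, direct c' = "
          f"{med.paths['c_prime']:.4f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
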