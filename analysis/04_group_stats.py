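"""Group statistics: frequency-wise FDR, band t-test, ANOVAs, correlations.

Reads the online summaries and spectra written by scripts 02-03, generates
dyad-level questionnaire scores from the serial path model conditioned on
each dyad's realized band coupling, and runs the full statistical chain.
Writes results/scores.csv and results/stats.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from interbrain.io import RunConfig, write_scores_csv
from interbrain.offline import CouplingSpectrum
from interbrain.pipeline import generate_scores, stats_chain

RESULTS = Path(__file__).resolve().parents[1] / "results"


def load_spectra(path, freqs):
    df = pd.read_csv(path)
    cols = [f"f_{int(f)}" for f in freqs]
    return [CouplingSpectrum(r["dyad_id"], r["session"], freqs,
                             r[cols].to_numpy(dtype=float),
                             group=r["group"])
            for _, r in df.iterrows()]


def main() -> int:
    config = RunConfig.from_yaml(RESULTS / "config.yaml")
    online_df = pd.read_csv(RESULTS / "online.csv")
    band_df = pd.read_csv(RESULTS / "band_coupling.csv")
    spectra = load_spectra(RESULTS / "spectra.csv", config.freqs())

    scores = generate_scores(band_df, config)
    write_scores_csv(RESULTS / "scores.csv", scores)
    res = stats_chain(online_df, spectra, scores, config)
    (RESULTS / "stats.json").write_text(json.dumps(res, indent=2))

    print("frequency bins surviving FDR:",
          [int(f) for f in res["freqwise"]["significant_freqs"]])
    b = res["band"]
    print(f"band coupling (21-23 Hz): {b['variant']} t({b['df']:.2f}) = "
          f"{b['t']:.3f}, p = {b['p']:.2e}, d = {b['d']:.3f}")
    for outcome, name in (("sc", "social connectedness"),
                          ("si", "shared intentionality"),
                          ("ps", "perceived similarity")):
        a = res[f"anova_{outcome}"]
        print(f"{name}: time F(1,{a['time']['df2']:.0f}) = "
              f"{a['time']['F']:.3f} (eta_p^2 = "
              f"{a['time']['partial_eta_sq']:.3f}); interaction F = "
              f"{a['interaction']['F']:.3f} (p = "
              f"{a['interaction']['p']:.3f})")
    jc = res["joint_control"]
    print(f"joint control: t({jc['df']:.2f}) = {jc['t']:.3f}, "
          f"d = {jc['d']:.3f}")
    for k, (r, p) in res["correlations"].items():
        print(f"r({k}) = {r:.3f} (p = {p:.3f})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
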