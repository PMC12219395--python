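"""Group susceptibility chi(N): maximal response at the critical size.

Runs the paired pulse/control protocol over group sizes 2-70 (leader-
scale opposing pulses, 0.25-0.35 mN, evaluated tau = 5 s after the pulse)
and locates the peak of the normalised response curve.  The peak
coincides with the mean-field critical size N = 2*F_ind/f0 = 20 within
one grid step: small groups comply but forget, large groups ignore the
leader, near-critical groups amplify and retain the injected direction.

Writes results/susceptibility.csv and results/susceptibility_summary.json.
"""

import json
import pathlib
import sys

from antcargo.meanfield import critical_group_size
from antcargo.susceptibility import response_vs_N

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

REPS = 300
SEED = 7


def main() -> None:
    res = response_vs_N(N_grid=tuple(range(2, 71, 4)), reps=REPS, seed=SEED)
    res.table.to_csv(OUT / "susceptibility.csv", index=False,
                     float_format="%.6g")
    summary = dict(
        peak_N=res.peak_N,
        peak_tied=res.peak_tied,
        tau_s=res.tau,
        force_band_mN=list(res.force_band_mN),
        reps=REPS,
        meanfield_critical_N=critical_group_size(),
    )
    with open(OUT / "susceptibility_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(res.table.to_string(index=False,
                              formatters={"chi_rad": "{:.4f}".format,
                                          "chi_norm": "{:.3f}".format,
                                          "sem": "{:.4f}".format}))
    print(f"\nchi(N) peaks at N = {res.peak_N} "
          f"(mean-field critical size {critical_group_size():.0f}); "
          f"the curve rises through the disordered sizes and collapses in "
          f"the ordered regime.")
    print(f"wrote {OUT / 'susceptibility.csv'}")


if __name__ == "__main__":
    sys.exit(main())
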