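"""Compute the ten migration characteristics per track.

Consumes the regularized daily paths, re-runs segmentation internally,
and emits one row per track (distance, duration, start/end day of year,
directness, migration and travel speed, stopover usage) plus the
population and animal identifiers.  Writes results/metrics/summaries.csv
and prints the per-population means.
"""

import argparse
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from gullmig.pipeline import daily_paths_from_csv, summaries_table


def main(daily: str = "results/ssm/daily_paths.csv",
         manifest: str = "results/clean/manifest.csv",
         birds: str = "results/sim/birds.csv",
         out: str = "results/metrics") -> None:
    out_dir = pathlib.Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    dailies = daily_paths_from_csv(daily)
    man = pd.read_csv(manifest, dtype={"individual": str}).set_index("individual")
    bird_map = {}
    birds_path = pathlib.Path(birds)
    if birds_path.exists():
        bdf = pd.read_csv(birds_path, dtype=str)
        bird_map = dict(zip(bdf["individual"], bdf["bird"]))
    table = summaries_table(dailies, man, birds=bird_map)
    table.to_csv(out_dir / "summaries.csv", index=False)

    cols = ["migration_distance_km", "duration_days", "directness",
            "migration_speed_km_day", "travel_speed_km_day",
            "total_stopover_days"]
    means = table.groupby("population")[cols].agg(["mean", "std"]).round(1)
    print(f"{len(table)} migration summaries")
    print(means.to_string())


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--daily", default="results/ssm/daily_paths.csv")
    ap.add_argument("--manifest", default="results/clean/manifest.csv")
    ap.add_argument("--birds", default="results/sim/birds.csv")
    ap.add_argument("--out", default="results/metrics")
    a = ap.parse_args()
    main(a.daily, a.manifest, a.birds, a.out)
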