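"""Classify travel/stopover days and detect each autumn migration window.

Default thresholds: > 0.3 deg latitude in a consistent direction on 2
of 3 sliding-window transitions, or > 75 km in a single day; migration
starts with the travel period that finally leaves the 200 km colony
radius and ends with the travel period followed by winter residency.
Writes per-day labels and per-track windows under results/segmentation/.
"""

import argparse
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from gullmig.pipeline import daily_paths_from_csv, segment_all
from gullmig.segment import ClassifierConfig


def main(daily: str = "results/ssm/daily_paths.csv",
         manifest: str = "results/clean/manifest.csv",
         out: str = "results/segmentation",
         percentile_mode: bool = False) -> None:
    out_dir = pathlib.Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    dailies = daily_paths_from_csv(daily)
    man = pd.read_csv(manifest, dtype={"individual": str}).set_index("individual")
    cfg = ClassifierConfig(percentile_mode=percentile_mode)
    labels, windows = segment_all(dailies, man, cfg)
    labels.to_csv(out_dir / "labels.csv", index=False)
    windows.to_csv(out_dir / "windows.csv", index=False)
    lab_counts = labels["label"].value_counts()
    print(f"{len(dailies)} tracks: {lab_counts.get('travel', 0)} travel days, "
          f"{lab_counts.get('stopover', 0)} stopover days; "
          f"{int(windows['detected'].sum())}/{len(windows)} windows detected")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--daily", default="results/ssm/daily_paths.csv")
    ap.add_argument("--manifest", default="results/clean/manifest.csv")
    ap.add_argument("--out", default="results/segmentation")
    ap.add_argument("--percentile-mode", action="store_true")
    a = ap.parse_args()
    main(a.daily, a.manifest, a.out, a.percentile_mode)
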