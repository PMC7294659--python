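"""Preprocess raw tracks: duplicate removal and the 200 km/h speed filter.

Reads results/sim/, writes cleaned Movebank-dialect CSVs to
results/clean/ and reports how many fixes each step removed.
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from gullmig import trackio


def main(inp: str = "results/sim", out: str = "results/clean",
         vmax: float = 200.0) -> None:
    out_dir = pathlib.Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracks = trackio.read_tracks(pathlib.Path(inp) / "fixes.csv",
                                 pathlib.Path(inp) / "manifest.csv")
    n_raw = sum(len(t) for t in tracks)
    deduped = [trackio.deduplicate(t) for t in tracks]
    n_dedup = sum(len(t) for t in deduped)
    clean = [trackio.speed_filter(t, vmax=vmax) for t in deduped]
    n_clean = sum(len(t) for t in clean)
    trackio.write_tracks(clean, out_dir / "fixes.csv", out_dir / "manifest.csv")
    print(f"{n_raw} raw fixes -> {n_dedup} after deduplication "
          f"-> {n_clean} after the {vmax:.0f} km/h speed filter "
          f"({n_raw - n_clean} removed)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="inp", default="results/sim")
    ap.add_argument("--out", default="results/clean")
    ap.add_argument("--vmax", type=float, default=200.0)
    a = ap.parse_args()
    main(a.inp, a.out, a.vmax)
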