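#!/usr/bin/env python
"""Opt-in reproduction on the PhysioNet CEBS database ("cebsdb").

Not part of the test suite: it needs a locally downloaded copy of the
database (https://physionet.org/content/cebsdb/), e.g.

    wget -r -N -c -np https://physionet.org/files/cebsdb/1.0.0/
    python scripts/cebs_reproduction.py --cebs-dir physionet.org/files/cebsdb/1.0.0 \
        --out results/cebs_grid.csv

For every record it reads the .hea/.dat pair, downsamples to 1 kHz, cuts
five random 60-s episodes of the music-listening segment, and runs the
pipeline x detector grid, ranking combinations by mean |HR_SCG - HR_ECG|.
On this benchmark the sliding-window-max detector with the 8-16 Hz
(hamilton2002) pipeline is expected to rank first.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from scgbeat.detect import list_detectors
from scgbeat.evaluate import grid_to_frame, run_grid
from scgbeat.io import read_record
from scgbeat.preprocess import list_pipelines
from scgbeat.signals import resample_record


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cebs-dir", type=Path, required=True,
                    help="directory containing the cebsdb .hea/.dat files")
    ap.add_argument("--out", type=Path, default=Path("results/cebs_grid.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--max-records", type=int, default=20)
    args = ap.parse_args()

    headers = sorted(args.cebs_dir.glob("*.hea"))[: args.max_records]
    if not headers:
        raise SystemExit(f"no .hea files found in {args.cebs_dir}")
    records = []
    for hea in headers:
        rec = read_record(hea, format="wfdb")
        records.append(resample_record(rec, 1000.0))
        print(f"loaded {hea.stem}: {rec.duration_s:.0f} s at {rec.fs:.0f} Hz")

    pipelines = [p.name for p in list_pipelines()]
    detectors = [d for d in list_detectors() if not d.startswith("_")]
    rows = run_grid(records, pipelines, detectors,
                    episodes_per_record=5, episode_s=60.0, seed=args.seed)
    df = grid_to_frame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(df.head(15).to_string(index=False))
    print(f"\nfull table -> {args.out}")


if __name__ == "__main__":
    main()
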