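#!/usr/bin/env python
"""Benchmark both detectors on locally stored PhysioNet-style WFDB records.

This optional runner reproduces the dataset-level evaluation tables on real
archived ECG data.  It never downloads anything itself: fetch the records
first (for example the MIT-BIH Arrhythmia Database, https://doi.org/10.13026/C2F305,
and the MIT-BIH Normal Sinus Rhythm Database, https://doi.org/10.13026/C2NK5R,
both freely available from PhysioNet) into a directory, then describe them
in a manifest YAML:

    max_minutes: 30          # optional per-record cap (e.g. sinus records)
    entries:
      - record: 100          # basename of 100.hea/100.dat/100.atr
      - record: 101
    exclude:
      - {record: 102, reason: unreliable waveform}

and run, from the repository root:

    python scripts/physionet_bench.py --manifest data/manifest.yaml \
        --out-dir results/physionet [--mode resample200] [--tolerance-ms 150]

For each detector it writes per-record peak lists, metric tables under both
aggregation bases (pooled counts and per-record means), and an
operation-count summary into ``--out-dir``.
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

from ampt.evaluation import DEFAULT_TOLERANCE_MS
from ampt.pipeline import DatasetManifest, run_pipeline


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        description=__doc__,
        formatter_class=argparse.RawDescriptionHelpFormatter)
    parser.add_argument("--manifest", type=Path, required=True,
                        help="Manifest YAML listing the WFDB records.")
    parser.add_argument("--out-dir", type=Path, required=True)
    parser.add_argument("--mode", choices=["native", "resample200"],
                        default="native")
    parser.add_argument("--tolerance-ms", type=float,
                        default=DEFAULT_TOLERANCE_MS)
    args = parser.parse_args(argv)

    manifest = DatasetManifest.from_yaml(args.manifest)
    summary = {}
    exit_code = 0
    for detector in ("pt", "ampt"):
        out = run_pipeline(manifest, detector, args.mode,
                           args.tolerance_ms, args.out_dir)
        summary[detector] = {
            "pooled": out.pooled.as_row(),
            "per_record_mean": out.per_record_mean.as_row(),
            "op_counts": out.op_counts,
            "failures": out.failures,
        }
        if out.failures:
            exit_code = 2
    (args.out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    return exit_code


if __name__ == "__main__":
    sys.exit(main())
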