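#!/usr/bin/env python
"""Fetch the deposited structures needed by the benchmark tests (t3/t4).

Requires network access.  Files land in scratch/benchmarks/ (override with
NMRSCORE_BENCHMARK_DIR).  The complex-model file name inside the models
repository may change; pass --model-url to point directly at the raw PDB of
model A if the default guesses fail, or place it manually as model_A.pdb.
"""

from __future__ import annotations

import argparse
import os
import sys
import urllib.request
from pathlib import Path

REPO_ROOT = Path(__file__).resolve().parent.parent
BENCH_DIR = Path(os.environ.get("NMRSCORE_BENCHMARK_DIR",
                                REPO_ROOT / "scratch" / "benchmarks"))

RCSB = "https://files.rcsb.org/download/{}.pdb"
MODEL_REPO_RAW = ("https://raw.githubusercontent.com/LBC-LNBio/"
                  "MinC-FtsZ_models/main/{}")
MODEL_GUESSES = ["model_A.pdb", "Model_A.pdb", "modelA.pdb",
                 "FtsZ_MinC_model_A.pdb"]


def fetch(url: str, dest: Path) -> bool:
    try:
        print(f"fetching {url} -> {dest}")
        urllib.request.urlretrieve(url, dest)
        return True
    except Exception as exc:
        print(f"  failed: {exc}", file=sys.stderr)
        return False


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model-url", default=None,
                        help="Direct URL of the complex model A PDB.")
    args = parser.parse_args()
    BENCH_DIR.mkdir(parents=True, exist_ok=True)
    ok = True
    for entry in ("2M4I", "1HF2"):
        dest = BENCH_DIR / f"{entry}.pdb"
        if not dest.exists():
            ok &= fetch(RCSB.format(entry), dest)
    model = BENCH_DIR / "model_A.pdb"
    if not model.exists():
        urls = ([args.model_url] if args.model_url
                else [MODEL_REPO_RAW.format(g) for g in MODEL_GUESSES])
        if not any(fetch(u, model) for u in urls):
            print("could not fetch the complex model; download it manually "
                  f"and save as {model}", file=sys.stderr)
            ok = False
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
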