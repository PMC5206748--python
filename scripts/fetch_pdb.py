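#!/usr/bin/env python
"""Fetch the deposited coordinate files used by the structure analyses.

Downloads the antibody-cadherin complexes and dimer templates into
data/pdb/ so that the deposited-structure tests and analyses can run.
Requires network access to the structure archive.

Usage: python scripts/fetch_pdb.py [entry ...]
"""

import sys
import urllib.request
from pathlib import Path

ENTRIES = ["5jyl", "5jym", "4zmv", "4zml", "4zmy"]
URL = "https://files.rcsb.org/download/{}.pdb"
OUT = Path(__file__).resolve().parent.parent / "data" / "pdb"


def main() -> int:
    entries = [e.lower() for e in sys.argv[1:]] or ENTRIES
    OUT.mkdir(parents=True, exist_ok=True)
    failed = []
    for entry in entries:
        dest = OUT / f"{entry}.pdb"
        if dest.exists():
            print(f"{entry}: already present")
            continue
        try:
            urllib.request.urlretrieve(URL.format(entry.upper()), dest)
            print(f"{entry}: fetched -> {dest}")
        except Exception as exc:  # noqa: BLE001
            failed.append(entry)
            print(f"{entry}: FAILED ({exc})")
    if failed:
        print(f"could not fetch: {', '.join(failed)}")
        return 1
    print(
        "note: the enclosed-form X-dimer template has no public accession; "
        "place it manually as data/pdb/enc_x_dimer.pdb if available"
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
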