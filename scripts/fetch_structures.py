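#!/usr/bin/env python
"""Download the deposited transporter coordinate files used by the
regression checks into data/structures/.

Needs network access to files.rcsb.org.  The files are not bundled with the
package (full atomic models are large); the tests that compare against the
deposited models fail with a diagnostic until this script has been run.

Usage:  python scripts/fetch_structures.py [--dest data/structures]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

# AtAtm3 conformational states (inward apo / inward+GSSG / closed / outward)
# plus the comparison structures used for cross-species context and the
# outward-facing reference frame.
ACCESSIONS = ["7N58", "7N59", "7N5A", "7N5B", "2HYD", "4MYC", "6VQU", "6PAM", "6PAR"]
URL = "https://files.rcsb.org/download/{acc}.cif"


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", default="data/structures", type=Path)
    parser.add_argument("--accessions", nargs="*", default=ACCESSIONS)
    args = parser.parse_args(argv)
    args.dest.mkdir(parents=True, exist_ok=True)
    failures = []
    for acc in args.accessions:
        out = args.dest / f"{acc}.cif"
        if out.exists():
            print(f"{acc}: already present")
            continue
        try:
            urllib.request.urlretrieve(URL.format(acc=acc), out)
            print(f"{acc}: downloaded -> {out}")
        except Exception as exc:  # noqa: BLE001 - report and continue
            failures.append(acc)
            print(f"{acc}: FAILED ({exc})", file=sys.stderr)
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
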