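# Deposited coordinate files

This directory is populated by

    python scripts/fetch_structures.py

which downloads the deposited AtAtm3 coordinate files (PDB 7N58, 7N59,
7N5A, 7N5B) plus the comparison/reference structures (2HYD, 4MYC, 6VQU,
6PAM, 6PAR) from the wwPDB.  The files are not bundled with the package;
the regression tests that compare against them fail with a diagnostic
until they are present.
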