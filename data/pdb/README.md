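# Deposited crystal structures (not bundled)

The structural-reproduction tests compare against the deposited
ubiquitin crystal structures, which are not redistributed here.
To enable them, download the PDB-format coordinate files and place
them in this directory as:

    1ubq.pdb   wild-type ubiquitin
    4wzp.pdb   phosphorylated ubiquitin, native-like conformer
    5w46.pdb   S65D phosphomimetic ubiquitin

e.g. from https://files.rcsb.org/download/1UBQ.pdb (and likewise for
4WZP, 5W46). Without these files the corresponding acceptance tests
fail with a message pointing here; all other tests are self-contained.
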