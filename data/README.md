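# External sequence data

`uniprot_taar.fasta` (not shipped) holds the receptor panel used by the
printed-identity checks: UniProt accessions Q96RJ0, Q9P1P5, O14804,
Q96RI8, Q969N4, Q96RI9 (human TAAR1/2/5/6/8/9), Q923Y8 (mouse TAAR1),
Q5QD15 (mouse TAAR6) and zebrafish TAAR13c, with record ids
TAAR1_HUMAN, TAAR2_HUMAN, TAAR5_HUMAN, TAAR6_HUMAN, TAAR8_HUMAN,
TAAR9_HUMAN, TAAR1_MOUSE, TAAR6_MOUSE, TAAR13C_DANRE.  Fetch them from
https://www.uniprot.org and concatenate into this directory.
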