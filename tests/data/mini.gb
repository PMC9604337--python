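LOCUS       SYNMINI1                 400 bp    DNA     circular UNK 01-JAN-1980
DEFINITION  synthetic mini mitogenome fragment for parser tests.
ACCESSION   SYNMINI1
VERSION     SYNMINI1
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
FEATURES             Location/Qualifiers
     CDS             1..90
                     /gene="ND2"
     tRNA            complement(95..160)
                     /product="tRNA-Leu(UUR)"
     rRNA            complement(165..300)
                     /product="16S ribosomal RNA"
     D-loop          305..400
                     /note="control region"
ORIGIN
        1 atgaattatt gatatgtatg aacgaacttg ttattattag agataaaacc aaacgctgat
       61 ctgccacgtc cgcgacgtca atacatttaa tttaacataa gctacgtata taaacaggta
      121 tgttaacgaa gtaattataa tataattcaa aatattcatt ataaatatac atcctcttgt
      181 gagaataatc ctttcaaaaa taccaaattc cacttaatct cattctaaac ttgtgtagtt
      241 ttaaagcaac gtctgctatt taacaactta taatataatc tcaaaaaatt ctgttcatcc
      301 aggccgctat atcatatttg gaattgatta taatgggttt attaaaaaac actaatcatt
      361 caaatacgtt aaatactatt gcgtaaaatt acctacgttt
//
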