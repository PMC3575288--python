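CC   Miniature restriction-enzyme collection in the Bairoch-style REBASE
CC   flat dialect, assembled for offline use (synthetic subset; sites match
CC   the public record, supplier codes are illustrative).
CC   REBASE version mini-1
CC   Fields: ID enzyme name; RS recognition site (cut annotations with ^ or
CC   (n/m) are allowed); CR commercial source letter codes; // ends a record.
ID   AatII
RS   GACGT^C;
CR   NOR.
//
ID   AflII
RS   C^TTAAG;
CR   NK.
//
ID   AflIII
RS   A^CRYGT;
CR   N.
//
ID   AgeI
RS   A^CCGGT;
CR   NR.
//
ID   ApaI
RS   GGGCC^C;
CR   NBKR.
//
ID   ApoI
RS   R^AATTY;
CR   N.
//
ID   AvrII
RS   C^CTAGG;
CR   N.
//
ID   BamHI
RS   G^GATCC;
CR   NBKMQRSX.
//
ID   BglII
RS   A^GATCT;
CR   NBKMQRS.
//
ID   BsaI
RS   GGTCTC(1/5);
CR   N.
//
ID   BsrGI
RS   T^GTACA;
CR   N.
//
ID   BstXI
RS   CCANNNNN^NTGG;
CR   NBKMQ.
//
ID   ClaI
RS   AT^CGAT;
CR   NBKMR.
//
ID   DdeI
RS   C^TNAG;
CR   NKR.
//
ID   DraI
RS   TTT^AAA;
CR   NBKMQRS.
//
ID   EagI
RS   C^GGCCG;
CR   N.
//
ID   EcoRI
RS   G^AATTC;
CR   NBJKMOQRSXY.
//
ID   EcoRV
RS   GAT^ATC;
CR   NBJKMOQRSX.
//
ID   FseI
RS   GGCCGG^CC;
CR   N.
//
ID   HincII
RS   GTY^RAC;
CR   NKORX.
//
ID   HindIII
RS   A^AGCTT;
CR   NBJKMOQRSXY.
//
ID   HpaI
RS   GTT^AAC;
CR   NBKMQRSX.
//
ID   KpnI
RS   GGTAC^C;
CR   NBJKMOQRSX.
//
ID   MfeI
RS   C^AATTG;
CR   N.
//
ID   MluI
RS   A^CGCGT;
CR   NBKMQRS.
//
ID   NcoI
RS   C^CATGG;
CR   NBKMQRS.
//
ID   NdeI
RS   CA^TATG;
CR   NBKMQRS.
//
ID   NheI
RS   G^CTAGC;
CR   NBKMQRS.
//
ID   NotI
RS   GC^GGCCGC;
CR   NBJKMOQRSX.
//
ID   NsiI
RS   ATGCA^T;
CR   NBKMQ.
//
ID   PacI
RS   TTAAT^TAA;
CR   N.
//
ID   PmlI
RS   CAC^GTG;
CR   N.
//
ID   PstI
RS   CTGCA^G;
CR   NBJKMOQRSXY.
//
ID   PvuII
RS   CAG^CTG;
CR   NBJKMOQRSX.
//
ID   SacI
RS   GAGCT^C;
CR   NBJKMOQRSX.
//
ID   SalI
RS   G^TCGAC;
CR   NBJKMOQRSX.
//
ID   ScaI
RS   AGT^ACT;
CR   NBJKMQRS.
//
ID   SmaI
RS   CCC^GGG;
CR   NBJKMOQRSXY.
//
ID   SpeI
RS   A^CTAGT;
CR   NBKQRS.
//
ID   SphI
RS   GCATG^C;
CR   NBKMOQRS.
//
ID   StuI
RS   AGG^CCT;
CR   NBJKMQ.
//
ID   Uba1394I
RS   GGATC;
//
ID   XbaI
RS   T^CTAGA;
CR   NBJKMOQRSX.
//
ID   XhoI
RS   C^TCGAG;
CR   NBJKMOQRS.
//
ID   XmaI
RS   C^CCGGG;
CR   NQ.
//
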