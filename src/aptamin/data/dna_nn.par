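## aptamin DNA nearest-neighbor parameter file v1
## All free energies in 0.01 kcal/mol at 37 C. INF = forbidden.

# pairs
/* allowed base pairs, 5' base first */
CG GC AT TA

# stack
/* rows: outer pair (i,j); columns: inner pair (k,l) */
/*        CG      GC      AT      TA */
   -184   -217   -145   -128   /* CG */
   -224   -184   -130   -144   /* GC */
   -144   -128   -100    -88   /* AT */
   -130   -145    -58   -100   /* TA */

# hairpin
   INF    INF    350    350    330    400    420    430    450    460
   480    500    505    510    520    530    540    550    560    570
   580    585    595    605    610    615    620    620    625    630

# bulge
   400    290    310    320    330    350    370    390    410    430
   440    450    465    480    490    500    510    520    525    530
   535    545    550    555    560    565    575    580    585    590

# interior
   INF    320    320    360    400    440    460    480    490    500
   510    520    530    540    550    560    570    580    585    590
   600    605    615    625    630    635    645    650    655    660

# ML_params
/* closing penalty a; per-helix b (incl. closing); per-unpaired c */
   340     40      0

# NINIO
/* per-nt asymmetry penalty; cap */
    30    300

# Misc
/* terminal_AT  lxc(long-loop ln coefficient)  temperature_C */
     5    150     37

# END
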