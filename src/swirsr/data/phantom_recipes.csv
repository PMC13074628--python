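label,il_stock_pct,m_water_g,m_gelatin_g,m_il_g,true_water_content_pct
70% AW,10,10.50,3.000,1.50,78.00
73.68% AW,10,11.052,2.448,1.50,81.68
75% AW,10,11.25,2.250,1.50,83.00
80% AW,10,12.00,1.500,1.50,88.00
62% AW,20,9.300,2.700,3.00,78.00
65.68% AW,20,9.852,2.148,3.00,81.68
67% AW,20,10.050,1.950,3.00,83.00
72% AW,20,10.800,1.200,3.00,88.00
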