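response,species,low,high,source_section
yield,TM,178.41,326.68,reported-range
yield,ZM,111.88,177.03,reported-range
protein,TM,37.27,42.34,reported-range
protein,ZM,33.94,42.82,reported-range
crude_fat,TM,24.83,33.54,reported-range
crude_fat,ZM,32.35,44.48,reported-range
crude_ash,TM,3.20,5.10,synthetic-default
crude_ash,ZM,2.10,3.40,synthetic-default
crude_fiber,TM,5.28,9.12,reported-range
crude_fiber,ZM,5.28,9.12,reported-range
digestibility,TM,83.05,85.59,reported-range
digestibility,ZM,82.05,84.05,reported-range
Thr,TM,3.50,4.50,synthetic-default
Thr,ZM,3.50,4.50,synthetic-default
Val,TM,5.00,6.50,synthetic-default
Val,ZM,5.00,6.50,synthetic-default
Met,TM,1.00,1.60,synthetic-default
Met,ZM,1.00,1.60,synthetic-default
Ile,TM,4.00,5.20,synthetic-default
Ile,ZM,4.00,5.20,synthetic-default
Leu,TM,7.00,9.50,synthetic-default
Leu,ZM,7.00,9.50,synthetic-default
Tyr,TM,5.00,7.00,synthetic-default
Tyr,ZM,5.00,7.00,synthetic-default
Phe,TM,3.00,4.20,synthetic-default
Phe,ZM,3.00,4.20,synthetic-default
His,TM,2.50,3.60,synthetic-default
His,ZM,2.50,3.60,synthetic-default
Lys,TM,5.50,7.00,synthetic-default
Lys,ZM,5.50,7.00,synthetic-default
Ca,TM,24.30,32.28,reported-range
Ca,ZM,38.68,66.85,reported-range
K,TM,741.74,878.14,reported-range
K,ZM,493.19,665.71,reported-range
Mg,TM,181.19,277.14,reported-range
Mg,ZM,71.95,100.98,reported-range
Na,TM,130.00,180.00,synthetic-default
Na,ZM,130.00,180.00,synthetic-default
P,TM,751.56,915.80,reported-range
P,ZM,541.14,651.15,reported-range
C18_2n6c,TM,22.00,33.00,synthetic-default
C18_2n6c,ZM,18.00,28.00,synthetic-default
C18_3n3,TM,0.90,16.00,synthetic-default
C18_3n3,ZM,0.90,16.00,synthetic-default
n6_n3,TM,1.6,26.9,reported-range
n6_n3,ZM,1.4,21.4,reported-range
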