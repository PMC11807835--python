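country,l3_code
Argentina,AGE
Argentina,AGS
Argentina,AGW
Australia,NSW
Australia,NTA
Australia,QLD
Australia,SOA
Australia,TAS
Australia,VIC
Australia,WAU
Austria,AUT
Belgium,BGM
Canada,ABT
Canada,BRC
Canada,LAB
Canada,MAN
Canada,NBR
Canada,NFL
Canada,NSC
Canada,NUN
Canada,NWT
Canada,ONT
Canada,PEI
Canada,QUE
Canada,SAS
Canada,YUK
Colombia,CLM
Denmark,DEN
France,COR
France,FRA
Germany,GER
Latvia,LAT
Mexico,MXC
Mexico,MXE
Mexico,MXG
Mexico,MXI
Mexico,MXN
Mexico,MXP
Mexico,MXS
Mexico,MXT
New Zealand,NZN
New Zealand,NZS
Norway,NOR
South Africa,CPP
South Africa,NAT
South Africa,OFS
South Africa,TVL
Spain,BAL
Spain,CNY
Spain,SPA
Sweden,SWE
Switzerland,SWI
United Kingdom,GRB
United Kingdom,IRE
United States,ALA
United States,ALU
United States,ARI
United States,ARK
United States,ASK
United States,CAL
United States,CNT
United States,COL
United States,DEL
United States,FLA
United States,GEO
United States,HAW
United States,IDA
United States,ILL
United States,INI
United States,IOW
United States,KAN
United States,KTY
United States,LOU
United States,MAI
United States,MAS
United States,MIC
United States,MIN
United States,MNT
United States,MRY
United States,MSI
United States,MSO
United States,NCA
United States,NDA
United States,NEB
United States,NEV
United States,NWH
United States,NWJ
United States,NWM
United States,NWY
United States,OHI
United States,OKL
United States,ORE
United States,PEN
United States,RHO
United States,SCA
United States,SDA
United States,TEN
United States,TEX
United States,UTA
United States,VER
United States,VRG
United States,WAS
United States,WDC
United States,WIS
United States,WVA
United States,WYO
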