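product_id,atc_code,vaccine_name,pack_size_ml,dose_ml,admin_type,auth_start_year,auth_end_year
480101,QI10AB04,Alpha Erm Salar Bath,1000,,bath,2016,
556139,QI10AB04,Alpha Erm Salar,250,0.025,injection,2020,
429437,QI10AB04,Alpha Erm Salar,500,0.025,injection,2021,
130772,QI10AB02,Alpha Ject 3000,500,0.1,injection,2009,
101148,QI10AB03,Alpha Ject 5-3,500,0.1,injection,2011,
101159,QI10AL02,Alpha Ject 6-2,500,0.1,injection,2010,
027475,QI10AL02,Alpha Ject Micro 6,500,0.05,injection,2011,
027464,QI10AL02,Alpha Ject Micro 6,250,0.05,injection,2011,
034501,QI10AA01,Alpha Ject micro 1 PD,500,0.05,injection,2017,
034490,QI10AA01,Alpha Ject micro 1 PD,250,0.05,injection,2017,
167812,QI10AB03,Alpha Ject micro 5,500,0.05,injection,2022,
465067,QI10AL04,Alpha Ject micro 7 ILA,500,0.05,injection,2019,
090235,QI10AL04,Alpha Ject micro 7 ILA,250,0.05,injection,2019,
560340,QI10AL02,Aquavac 6,500,0.1,injection,2016,2023
189864,QI10AA01,Aquavac PD,500,0.1,injection,2017,2021
193107,QI10AL05,Aquavac PD7,500,0.1,injection,2015,
061902,QI10BB03,Aquavac Relera Bath,1000,,bath,2012,2023
472689,QI10AA02,Clynav,250,0.05,injection,2018,
169401,QI10BB02,Lipogen Duo,500,0.1,injection,2006,2018
130420,QI10BB02,Lipogen Duo,1000,0.1,injection,2006,2018
515591,QI10AA01,Norvax Compact PD,500,0.1,injection,2012,2022
099126,QI10AL02,Norvax Minova 6,500,0.1,injection,2010,2017
130519,QI10AL02,Pentium Forte Plus,500,0.1,injection,2007,
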