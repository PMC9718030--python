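# 2019 annual-mean PM2.5, adult population and crude adult death rate for the
# 11-province Vietnamese study region (GSO 2019 census; A6 death registration,
# injury deaths excluded). Exposure is the district-aggregated annual mean of
# a 3x3 km modelled surface.
# file version: 1
province,pm25_annual_mean,population_25plus,death_rate_25plus_per_1000
Ha Noi,40.8,4889379,4.6
Bac Ninh,37.8,812711,5.4
Hung Yen,35.2,789408,4.1
Ha Nam,31.5,543823,7.9
Hai Duong,31.2,1222568,4.3
Thai Binh,27.1,1237051,8.3
Hai Phong,25.8,1311556,7.4
Ninh Binh,23.5,622278,7.8
Ho Chi Minh,20.9,5795749,4.8
Quang Ninh,18.9,825247,5.8
Dien Bien,15.8,293066,6.3
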