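area,n_counties,freq_early,rate_early,freq_advanced,rate_advanced,freq_mortality,rate_mortality
San Francisco,5,31003,164.3,23054,122.1,9032,47.9
Connecticut,8,30138,176.0,20912,122.1,9357,54.7
Atlanta,5,16345,142.9,12975,113.4,4787,41.9
Hawaii,5,9231,166.5,5920,106.8,1841,33.2
Iowa,99,22101,153.7,17182,119.5,7777,54.1
Detroit,3,29867,155.9,24295,126.8,11144,58.2
New Mexico,33,9697,123.5,8190,104.3,3324,42.4
Utah,29,9610,128.3,7964,106.3,2963,39.5
Seattle,13,31582,176.4,21846,122.0,7458,41.7
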